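"""Reward schedules and the trial-level data model for the pirate task.

The task is a two-armed probabilistic bandit with a volatility
manipulation: an 80-trial *stable* block in which one stimulus (red) is
rewarded on a fixed 75% of trials, and an 80-trial *volatile* block in
which the dominant stimulus is rewarded on 80% of trials within each
20-trial sub-block and the dominant side reverses between sub-blocks.
Exactly one stimulus is rewarded per trial; the displayed point values
for the two chests always sum to ``points_total`` and carry no
information about reward probability.

Reward sequences are exact-count designs (a seeded shuffle of a fixed
number of reward assignments), not i.i.d. Bernoulli draws, so the stated
ratios hold exactly within every block for every seed.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from . import _rng
from .errors import ConfigurationError, ParseError

STIMULI = ("red", "blue")
CONDITIONS = ("stable", "volatile")
ORDERS = ("stable_first", "volatile_first")

#: Canonical column order of the trial CSV.
TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "condition",
    "block_index",
    "rewarded_stimulus",
    "points_red",
    "points_blue",
    "choice",
    "chosen_rewarded",
    "points_won",
]


def _check_integral(value: float, field: str) -> int:
    if abs(value - round(value)) > 1e-9:
        raise ConfigurationError(f"{field}: expected count {value!r} is not an integer")
    return int(round(value))


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one task session.

    Defaults reproduce the standard session: 160 main trials (80 stable
    at 75:25, then 80 volatile at 80:20 reversing every 20 trials) after
    20 familiarisation trials at 80:20, with point splits summing to 100.
    """

    n_stable_trials: int = 80
    n_volatile_trials: int = 80
    stable_ratio: float = 0.75
    volatile_ratio: float = 0.80
    switch_interval: int = 20
    order: str = "stable_first"
    n_familiarisation: int = 20
    familiarisation_ratio: float = 0.80
    points_total: int = 100
    #: which stimulus the first volatile sub-block favours
    volatile_start: str = "red"

    def __post_init__(self) -> None:
        for field in ("n_stable_trials", "n_volatile_trials", "switch_interval", "n_familiarisation"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(f"{field}: must be positive")
        if self.points_total <= 0:
            raise ConfigurationError("points_total: must be positive")
        if self.order not in ORDERS:
            raise ConfigurationError(f"order: {self.order!r} not in {ORDERS}")
        if self.volatile_start not in STIMULI:
            raise ConfigurationError(f"volatile_start: {self.volatile_start!r} not in {STIMULI}")
        for field in ("stable_ratio", "volatile_ratio", "familiarisation_ratio"):
            r = getattr(self, field)
            if not (0.0 < r <= 1.0):
                raise ConfigurationError(f"{field}: {r!r} outside (0, 1]")
        if self.n_volatile_trials % self.switch_interval != 0:
            raise ConfigurationError(
                "n_volatile_trials: must be an integer multiple of switch_interval "
                f"({self.n_volatile_trials} vs {self.switch_interval})"
            )
        _check_integral(self.stable_ratio * self.n_stable_trials, "stable_ratio")
        _check_integral(self.volatile_ratio * self.switch_interval, "volatile_ratio")
        _check_integral(self.familiarisation_ratio * self.n_familiarisation, "familiarisation_ratio")

    @property
    def n_trials(self) -> int:
        return self.n_stable_trials + self.n_volatile_trials

    @property
    def n_volatile_blocks(self) -> int:
        return self.n_volatile_trials // self.switch_interval


@dataclass(frozen=True)
class ScheduleTrial:
    """One trial of the reward schedule (no behaviour attached)."""

    trial_index: int
    condition: str
    block_index: Optional[int]
    rewarded_stimulus: str
    points_red: int
    points_blue: int


@dataclass(frozen=True)
class TrialRecord:
    """One participant-trial: the schedule plus observed behaviour.

    ``choice`` may be ``None`` for a pure schedule row.  When a choice is
    present, ``chosen_rewarded`` is 1 iff the choice matched the rewarded
    stimulus and ``points_won`` is the chosen chest's displayed value if
    rewarded, else 0.
    """

    participant_id: str
    trial_index: int
    condition: str
    block_index: Optional[int]
    rewarded_stimulus: str
    points_red: int
    points_blue: int
    choice: Optional[str] = None
    chosen_rewarded: Optional[int] = None
    points_won: Optional[int] = None

    def validate(self, points_total: int = 100, row: Optional[int] = None) -> None:
        where = "" if row is None else f"row {row}: "
        if self.condition not in CONDITIONS:
            raise ParseError(f"{where}unknown condition {self.condition!r}")
        if self.rewarded_stimulus not in STIMULI:
            raise ParseError(f"{where}unknown rewarded_stimulus {self.rewarded_stimulus!r}")
        if self.points_red + self.points_blue != points_total:
            raise ParseError(
                f"{where}points_red + points_blue = {self.points_red + self.points_blue}, "
                f"expected {points_total}"
            )
        if self.choice is not None:
            if self.choice not in STIMULI:
                raise ParseError(f"{where}unknown choice {self.choice!r}")
            expected = int(self.choice == self.rewarded_stimulus)
            if self.chosen_rewarded != expected:
                raise ParseError(f"{where}chosen_rewarded inconsistent with choice/rewarded_stimulus")
            if self.chosen_rewarded == 0 and self.points_won != 0:
                raise ParseError(f"{where}points_won must be 0 on unrewarded trials")


def _exact_count_assignment(n: int, n_hits: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector with exactly ``n_hits`` True, positions shuffled."""
    hits = np.zeros(n, dtype=bool)
    hits[:n_hits] = True
    rng.shuffle(hits)
    return hits


def _points(n: int, points_total: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, points_total + 1, size=n)


def generate_schedule(config: TaskConfig, seed: int) -> List[ScheduleTrial]:
    """Generate one seeded session schedule.

    Reward assignments are exact-count within the stable block and within
    each volatile sub-block; point splits are independent uniform
    integers on [0, points_total] for red with blue as the complement.
    The stable and volatile blocks consume independent substreams of the
    master seed, so the two counterbalance orders are block permutations
    of one another under the same seed.
    """
    # stable block
    rng_s = _rng.substream(seed, _rng.STABLE_REWARDS)
    n_red = int(round(config.stable_ratio * config.n_stable_trials))
    stable_red = _exact_count_assignment(config.n_stable_trials, n_red, rng_s)
    stable_points = _points(config.n_stable_trials, config.points_total,
                            _rng.substream(seed, _rng.STABLE_POINTS))

    # volatile block: dominant stimulus alternates between sub-blocks
    rng_v = _rng.substream(seed, _rng.VOLATILE_REWARDS)
    n_dom = int(round(config.volatile_ratio * config.switch_interval))
    vol_red = np.zeros(config.n_volatile_trials, dtype=bool)
    vol_block = np.zeros(config.n_volatile_trials, dtype=int)
    for b in range(config.n_volatile_blocks):
        dominant_red = (b % 2 == 0) == (config.volatile_start == "red")
        hits = _exact_count_assignment(config.switch_interval, n_dom, rng_v)
        sl = slice(b * config.switch_interval, (b + 1) * config.switch_interval)
        vol_red[sl] = hits if dominant_red else ~hits
        vol_block[sl] = b
    vol_points = _points(config.n_volatile_trials, config.points_total,
                         _rng.substream(seed, _rng.VOLATILE_POINTS))

    def block(cond, red, points, blocks):
        return [
            (cond, None if blocks is None else int(blocks[i]),
             "red" if red[i] else "blue", int(points[i]))
            for i in range(len(red))
        ]

    rows = block("stable", stable_red, stable_points, None)
    vrows = block("volatile", vol_red, vol_points, vol_block)
    ordered = rows + vrows if config.order == "stable_first" else vrows + rows
    return [
        ScheduleTrial(
            trial_index=t,
            condition=cond,
            block_index=bi,
            rewarded_stimulus=rs,
            points_red=pr,
            points_blue=config.points_total - pr,
        )
        for t, (cond, bi, rs, pr) in enumerate(ordered)
    ]


def generate_familiarisation(config: TaskConfig, seed: int) -> List[ScheduleTrial]:
    """Passive familiarisation schedule on a distinct stimulus pair.

    The stimuli are labelled red/blue in the returned records for CSV
    compatibility (the familiarisation pair is a different colour pair on
    screen); the frequent stimulus occupies the red slot.
    """
    rng = _rng.substream(seed, _rng.FAMILIARISATION)
    n_hits = int(round(config.familiarisation_ratio * config.n_familiarisation))
    frequent = _exact_count_assignment(config.n_familiarisation, n_hits, rng)
    points = _points(config.n_familiarisation, config.points_total,
                     _rng.substream(seed, _rng.FAMILIARISATION_POINTS))
    return [
        ScheduleTrial(
            trial_index=t,
            condition="stable",
            block_index=None,
            rewarded_stimulus="red" if frequent[t] else "blue",
            points_red=int(points[t]),
            points_blue=config.points_total - int(points[t]),
        )
        for t in range(config.n_familiarisation)
    ]


# ---------------------------------------------------------------------------
# serialization


def trials_to_frame(records: Iterable[Union[TrialRecord, ScheduleTrial]],
                    participant_id: str = "") -> pd.DataFrame:
    """Convert trial dataclasses to the canonical DataFrame layout."""
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        if "participant_id" not in d:
            d["participant_id"] = participant_id
            d.setdefault("choice", None)
            d.setdefault("chosen_rewarded", None)
            d.setdefault("points_won", None)
        rows.append(d)
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df


def frame_to_trials(df: pd.DataFrame) -> List[TrialRecord]:
    records = []
    for _, row in df.iterrows():
        choice = row.get("choice")
        has_choice = isinstance(choice, str) and choice != ""
        bi = row.get("block_index")
        records.append(
            TrialRecord(
                participant_id=str(row["participant_id"]),
                trial_index=int(row["trial_index"]),
                condition=str(row["condition"]),
                block_index=None if pd.isna(bi) else int(bi),
                rewarded_stimulus=str(row["rewarded_stimulus"]),
                points_red=int(row["points_red"]),
                points_blue=int(row["points_blue"]),
                choice=choice if has_choice else None,
                chosen_rewarded=None if not has_choice else int(row["chosen_rewarded"]),
                points_won=None if not has_choice else int(row["points_won"]),
            )
        )
    return records


def validate_trials(df: pd.DataFrame, points_total: int = 100) -> pd.DataFrame:
    """Validate a trial DataFrame against the data-model invariants.

    Raises :class:`ParseError` naming the first offending column or row.
    Returns the validated frame (unchanged).
    """
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}")
    for i, rec in enumerate(frame_to_trials(df)):
        rec.validate(points_total=points_total, row=i)
    return df


def write_trials(records, destination) -> None:
    """Write trials (dataclasses or a DataFrame) to a headered CSV."""
    if isinstance(records, pd.DataFrame):
        df = records[TRIAL_COLUMNS]
    else:
        df = trials_to_frame(records)
    df.to_csv(destination, index=False)


def read_trials(source) -> List[TrialRecord]:
    """Read and validate a trial CSV; returns TrialRecord objects.

    Use :func:`read_trials_frame` for the DataFrame form consumed by the
    modelling layer.
    """
    return frame_to_trials(read_trials_frame(source))


def read_trials_frame(source, points_total: int = 100) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = pd.read_csv(source)
    validate_trials(df, points_total=points_total)
    return df
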