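"""The cognitive model ladder: value updates, choice rules, likelihoods.

All delta-rule models track a single quantity ``v_red`` — the estimated
probability that the red stimulus is the rewarded one — with blue's
value as the complement (exactly one stimulus is rewarded per trial and
the rewarded stimulus is revealed after every choice).  The prediction
error is defined relative to the *chosen* stimulus:

    delta = r - V_chosen,    r = 1 if the choice was rewarded else 0,

and the learning rate applied to the update may depend on the sign of
delta (valence) and on the volatility condition, as dictated by each
model's ``lr_split``.  Choices follow a softmax on the value difference,

    p(red) = 1 / (1 + exp(-(v_red - v_blue) / tau)),

so a larger temperature ``tau`` means more exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .task import ScheduleTrial, TrialRecord

FAMILIES = ("null", "wsls", "delta_rule")
LR_SPLITS = ("none", "fixed_one", "single", "by_valence", "by_condition", "by_valence_and_condition")
TEMPERATURE_SPLITS = ("none", "shared", "by_condition")

#: learning-rate cell order used throughout the package:
#: (positive, stable), (negative, stable), (positive, volatile), (negative, volatile)
LR_CELLS = ("alpha_pos_stable", "alpha_neg_stable", "alpha_pos_volatile", "alpha_neg_volatile")


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the model ladder."""

    model_id: str
    family: str
    lr_split: str
    temperature_split: str
    parameter_names: Tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family: {self.family!r} not in {FAMILIES}")
        if self.lr_split not in LR_SPLITS:
            raise ConfigurationError(f"lr_split: {self.lr_split!r} not in {LR_SPLITS}")
        if self.temperature_split not in TEMPERATURE_SPLITS:
            raise ConfigurationError(f"temperature_split: {self.temperature_split!r}")
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ConfigurationError("parameter_names: duplicates present")
        if self.family == "null" and self.n_params > 1:
            raise ConfigurationError("null family admits at most one parameter")
        if self.family == "wsls" and self.n_params != 2:
            raise ConfigurationError("wsls family has exactly two parameters")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def alpha_name(self, condition: str, pe_sign: str) -> Optional[str]:
        """Name of the learning rate used for (condition, valence)."""
        if self.family != "delta_rule":
            raise ValidationError(f"{self.model_id}: no learning rates in family {self.family!r}")
        split = self.lr_split
        if split == "fixed_one":
            return None
        if split == "single":
            return "alpha"
        if split == "by_valence":
            return "alpha_pos" if pe_sign == "positive" else "alpha_neg"
        if split == "by_condition":
            return f"alpha_{condition}"
        return f"alpha_{'pos' if pe_sign == 'positive' else 'neg'}_{condition}"

    def temperature_name(self, condition: str) -> str:
        if self.temperature_split == "by_condition":
            return f"temperature_{condition}"
        return "temperature"


def _param_range_ok(name: str, value: float) -> bool:
    if name.startswith("temperature"):
        return value > 0
    return 0.0 < value < 1.0


@dataclass(frozen=True)
class AgentParams:
    """One participant's constrained parameters, bound to a model."""

    model_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.values.items():
            if not _param_range_ok(name, value):
                raise ConfigurationError(f"{name}: value {value!r} outside its admissible range")

    @classmethod
    def for_spec(cls, spec: ModelSpec, **values: float) -> "AgentParams":
        if set(values) != set(spec.parameter_names):
            raise ConfigurationError(
                f"{spec.model_id}: expected parameters {list(spec.parameter_names)}, got {sorted(values)}"
            )
        return cls(model_id=spec.model_id, values=dict(values))

    def __getattr__(self, name: str) -> float:
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.values[n] for n in spec.parameter_names], dtype=float)


@dataclass
class ValueState:
    """Estimated probability that red is the rewarded stimulus."""

    v_red: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.v_red <= 1.0):
            raise ValidationError(f"v_red {self.v_red!r} outside [0, 1]")

    @property
    def v_blue(self) -> float:
        return 1.0 - self.v_red


def initial_values() -> ValueState:
    return ValueState(0.5)


# ---------------------------------------------------------------------------
# model space


def enumerate_model_space(manifest: Optional[str] = None) -> List[ModelSpec]:
    """Load the 12-model ladder from the packaged (or a user) manifest."""
    if manifest is None:
        text = resources.files("volabandit").joinpath("data/model_space.yaml").read_text()
    else:
        with open(manifest) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    specs = [
        ModelSpec(
            model_id=m["model_id"],
            family=m["family"],
            lr_split=m["lr_split"],
            temperature_split=m["temperature_split"],
            parameter_names=tuple(m["parameter_names"]),
            description=m.get("description", ""),
        )
        for m in doc["models"]
    ]
    return specs


def get_spec(model_id: str, manifest: Optional[str] = None) -> ModelSpec:
    for spec in enumerate_model_space(manifest):
        if spec.model_id == model_id:
            return spec
    raise ConfigurationError(f"unknown model_id {model_id!r}")


# ---------------------------------------------------------------------------
# choice and update rules


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def choice_probability(state: ValueState, params: AgentParams, spec: ModelSpec,
                       condition: str = "stable") -> float:
    """Probability of choosing red on the next trial.

    For the delta-rule family this is the softmax of the value
    difference scaled by the (possibly condition-specific) temperature.
    For the null family it is 0.5 (or the bias parameter).  The WSLS
    family conditions on the previous trial and is handled by
    :func:`wsls_repeat_probability` / :func:`session_loglik`.
    """
    if spec.family == "null":
        return params["bias"] if "bias" in spec.parameter_names else 0.5
    if spec.family == "wsls":
        raise ValidationError("wsls choice probability depends on the previous trial; "
                              "use wsls_repeat_probability")
    tau = params[spec.temperature_name(condition)]
    if tau <= 0:
        raise ValidationError(f"temperature must be positive, got {tau!r}")
    return _sigmoid((state.v_red - state.v_blue) / tau)


def wsls_repeat_probability(params: AgentParams, previous_rewarded: int) -> float:
    """Probability of repeating the previous choice under WSLS."""
    if previous_rewarded:
        return params["stay_after_win"]
    return 1.0 - params["shift_after_loss"]


def _resolve_sign(pe_sign) -> str:
    if isinstance(pe_sign, str):
        if pe_sign not in ("positive", "negative"):
            raise ValidationError(f"pe_sign {pe_sign!r} not in {{positive, negative}}")
        return pe_sign
    # numeric prediction error: exact zero ties resolve to positive
    return "negative" if pe_sign < 0 else "positive"


def select_learning_rate(spec: ModelSpec, params: AgentParams, condition: str, pe_sign) -> float:
    """The learning rate the spec dictates for (condition, PE valence)."""
    if condition not in ("stable", "volatile"):
        raise ValidationError(f"condition {condition!r} not in {{stable, volatile}}")
    name = spec.alpha_name(condition, _resolve_sign(pe_sign))
    if name is None:  # fixed_one rung: full replacement by the last outcome
        return 1.0
    return params[name]


def update_values(state: ValueState, trial: TrialRecord, params: AgentParams,
                  spec: ModelSpec) -> ValueState:
    """Delta-rule update after one trial with a recorded choice.

    The chosen stimulus's value moves toward the realized outcome by the
    selected learning rate; the complement constraint keeps
    ``v_red + v_blue == 1`` exactly.
    """
    if trial.choice is None or trial.chosen_rewarded is None:
        raise ValidationError("update_values requires a trial with a recorded choice")
    v_c = state.v_red if trial.choice == "red" else state.v_blue
    delta = trial.chosen_rewarded - v_c
    alpha = select_learning_rate(spec, params, trial.condition, delta)
    v_c_new = v_c + alpha * delta
    v_red = v_c_new if trial.choice == "red" else 1.0 - v_c_new
    return ValueState(v_red=float(min(1.0, max(0.0, v_red))))


# ---------------------------------------------------------------------------
# session likelihood and simulation


def _as_records(trials) -> List[TrialRecord]:
    if isinstance(trials, pd.DataFrame):
        from .task import frame_to_trials

        return frame_to_trials(trials)
    return list(trials)


def session_loglik(spec: ModelSpec, params: AgentParams,
                   trials) -> Tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of one participant's session.

    ``trials`` must be a single participant's complete session in trial
    order, every trial carrying a choice.
    """
    records = _as_records(trials)
    if not records:
        return 0.0, np.zeros(0)
    pids = {r.participant_id for r in records}
    if len(pids) > 1:
        raise ValidationError(f"session_loglik expects one participant, got {sorted(pids)}")
    idx = [r.trial_index for r in records]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValidationError("trials must be in increasing trial_index order")
    if any(r.choice is None for r in records):
        raise ValidationError("every trial must carry a recorded choice")

    ll = np.zeros(len(records))
    if spec.family == "null":
        b = params["bias"] if "bias" in spec.parameter_names else 0.5
        for t, rec in enumerate(records):
            ll[t] = math.log(b if rec.choice == "red" else 1.0 - b)
    elif spec.family == "wsls":
        for t, rec in enumerate(records):
            if t == 0:
                ll[t] = math.log(0.5)
            else:
                prev = records[t - 1]
                p_rep = wsls_repeat_probability(params, prev.chosen_rewarded)
                repeated = rec.choice == prev.choice
                ll[t] = math.log(p_rep if repeated else 1.0 - p_rep)
    else:
        state = initial_values()
        for t, rec in enumerate(records):
            p_red = choice_probability(state, params, spec, rec.condition)
            ll[t] = math.log(p_red if rec.choice == "red" else 1.0 - p_red)
            state = update_values(state, rec, params, spec)
    return float(ll.sum()), ll


def simulate_agent(spec: ModelSpec, params: AgentParams,
                   schedule: Sequence[ScheduleTrial], seed: int,
                   participant_id: str = "sim") -> List[TrialRecord]:
    """Simulate one agent's choices on a schedule (seeded)."""
    rng = np.random.default_rng(seed)
    state = initial_values()
    records: List[TrialRecord] = []
    prev_choice: Optional[str] = None
    prev_rewarded: Optional[int] = None
    for trial in schedule:
        if spec.family == "wsls" and prev_choice is not None:
            p_rep = wsls_repeat_probability(params, prev_rewarded)
            p_red = p_rep if prev_choice == "red" else 1.0 - p_rep
        elif spec.family == "wsls":
            p_red = 0.5
        else:
            p_red = choice_probability(state, params, spec, trial.condition)
        choice = "red" if rng.random() < p_red else "blue"
        rewarded = int(choice == trial.rewarded_stimulus)
        points = (trial.points_red if choice == "red" else trial.points_blue) if rewarded else 0
        rec = TrialRecord(
            participant_id=participant_id,
            trial_index=trial.trial_index,
            condition=trial.condition,
            block_index=trial.block_index,
            rewarded_stimulus=trial.rewarded_stimulus,
            points_red=trial.points_red,
            points_blue=trial.points_blue,
            choice=choice,
            chosen_rewarded=rewarded,
            points_won=points,
        )
        records.append(rec)
        if spec.family == "delta_rule":
            state = update_values(state, rec, params, spec)
        prev_choice, prev_rewarded = choice, rewarded
    return records
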