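"""Synthetic cohorts: participants, task behaviour and SDQ questionnaires.

The study's raw data are not publicly available, so this module emulates
its structure: 121 participants aged 8-16 whose model parameters come
from a group-level distribution (Normal on the unconstrained scale —
logit for learning rates and other probabilities, log for temperature),
who each complete one 160-trial session, and who fill in the 25-item
Strengths and Difficulties Questionnaire (SDQ) with a configurable
planted association between a model parameter and the prosocial score.

Default group-level means place the four learning-rate cells at
0.475/0.745 (positive/negative, stable) and 0.575/0.845 (volatile) —
an additive decomposition of the reported condition and valence
marginals (stable 0.61, volatile 0.71; positive 0.53, negative 0.80) —
with cell-specific logit-scale spreads reproducing the printed
constrained SDs (0.09-0.15) and a median temperature of 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _rng
from ._likelihoods import constrain, simulate_choices, unconstrain
from .errors import ConfigurationError, ValidationError
from .models import AgentParams, ModelSpec
from .task import TRIAL_COLUMNS, TaskConfig, generate_schedule

#: constrained-scale group means used as simulation defaults (not truth)
REFERENCE_MEANS: Dict[str, float] = {
    "alpha_pos_stable": 0.475,
    "alpha_neg_stable": 0.745,
    "alpha_pos_volatile": 0.575,
    "alpha_neg_volatile": 0.845,
    "alpha_pos": 0.525,
    "alpha_neg": 0.795,
    "alpha_stable": 0.61,
    "alpha_volatile": 0.71,
    "alpha": 0.66,
    "temperature": 0.30,
    "temperature_stable": 0.30,
    "temperature_volatile": 0.30,
    "bias": 0.5,
    "stay_after_win": 0.8,
    "shift_after_loss": 0.7,
}

#: unconstrained-scale group spreads used as simulation defaults.
#: For the learning-rate cells these are the logit-scale values that map
#: the printed constrained SDs (stable .09, volatile .15, negative .11,
#: positive .13, averaged per cell) back through sigma_logit ~= SD / (m(1-m))
#: at the cell mean m; temperature spread is the package's own choice.
REFERENCE_SIGMAS: Dict[str, float] = {
    "alpha_pos_stable": 0.44,
    "alpha_neg_stable": 0.53,
    "alpha_pos_volatile": 0.57,
    "alpha_neg_volatile": 0.99,
    "alpha_pos": 0.52,
    "alpha_neg": 0.67,
    "alpha_stable": 0.38,
    "alpha_volatile": 0.73,
    "alpha": 0.45,
    "temperature": 0.40,
    "temperature_stable": 0.40,
    "temperature_volatile": 0.40,
    "bias": 0.50,
    "stay_after_win": 0.50,
    "shift_after_loss": 0.50,
}

AGE_CENTER = 12.0  # years; age slopes act on (age - AGE_CENTER)


@dataclass(frozen=True)
class ParamHyper:
    """Group-level hyperparameters for one parameter (unconstrained scale)."""

    mu: float
    sigma: float
    age_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma: must be positive, got {self.sigma!r}")


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level distribution over a model's parameters."""

    params: Mapping[str, ParamHyper]

    def names(self) -> Tuple[str, ...]:
        return tuple(self.params)

    def check_spec(self, spec: ModelSpec) -> None:
        if set(self.params) != set(spec.parameter_names):
            raise ConfigurationError(
                f"hyperparameters name {sorted(self.params)} but {spec.model_id} "
                f"has parameters {list(spec.parameter_names)}"
            )


def default_group_hyper(spec: ModelSpec, sigma_scale: float = 1.0) -> GroupHyperParams:
    """Reference-regime generating distribution for a model spec."""
    params = {}
    for name in spec.parameter_names:
        mean = np.array([REFERENCE_MEANS[name]])
        mu = float(unconstrain(mean, [name])[0])
        params[name] = ParamHyper(mu=mu, sigma=REFERENCE_SIGMAS[name] * sigma_scale)
    return GroupHyperParams(params=params)


@dataclass(frozen=True)
class Cohort:
    """A sampled set of participants bound to one model spec."""

    spec: ModelSpec
    ids: Tuple[str, ...]
    params: Tuple[AgentParams, ...]
    ages: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.params)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"participant_id": pid, "age": float(age), **p.values}
                for pid, p, age in zip(self.ids, self.params, self.ages)]
        return pd.DataFrame(rows)

    def theta(self) -> np.ndarray:
        """Constrained parameter matrix (n, n_params) in spec order."""
        return np.array([p.as_array(self.spec) for p in self.params])


def sample_cohort(hyper: GroupHyperParams, n: int, spec: ModelSpec, seed: int,
                  ages: Optional[Sequence[float]] = None) -> Cohort:
    """Draw ``n`` participants' parameters from the group distribution.

    Unconstrained values are Normal(mu + age_slope * (age - 12), sigma)
    per parameter, then mapped through the constraining transforms.
    Ages are uniform on [8, 16] when not supplied.
    """
    if n < 1:
        raise ConfigurationError("n: must be at least 1")
    hyper.check_spec(spec)
    rng = _rng.substream(seed, _rng.COHORT_PARAMS)
    if ages is None:
        ages_arr = rng.uniform(8.0, 16.0, size=n)
    else:
        ages_arr = np.asarray(ages, dtype=float)
        if ages_arr.shape != (n,):
            raise ConfigurationError(f"ages: expected {n} values, got shape {ages_arr.shape}")
    names = list(spec.parameter_names)
    z = np.empty((n, len(names)))
    for k, name in enumerate(names):
        h = hyper.params[name]
        loc = h.mu + h.age_slope * (ages_arr - AGE_CENTER)
        z[:, k] = loc + h.sigma * rng.standard_normal(n)
    theta = constrain(z, names)
    width = max(3, len(str(n)))
    ids = tuple(f"P{i + 1:0{width}d}" for i in range(n))
    params = tuple(
        AgentParams.for_spec(spec, **{name: float(theta[i, k]) for k, name in enumerate(names)})
        for i in range(n)
    )
    return Cohort(spec=spec, ids=ids, params=params, ages=ages_arr)


def simulate_cohort(cohort: Cohort, config: TaskConfig, seed: int,
                    shared_schedule: bool = False) -> pd.DataFrame:
    """Simulate every participant on the task; returns the trial table.

    Each participant gets a freshly randomized schedule from an
    independent substream (set ``shared_schedule`` to give everyone the
    same reward sequence and point splits).
    """
    n = len(cohort)
    schedules = []
    for i in range(n):
        sched_seed = _rng.child_seed(seed, _rng.COHORT_SCHEDULES, 0 if shared_schedule else i)
        schedules.append(generate_schedule(config, sched_seed))
    tmax = config.n_trials
    y = np.array([[s.rewarded_stimulus == "red" for s in sched] for sched in schedules], dtype=np.int8)
    cond = np.array([[s.condition == "volatile" for s in sched] for sched in schedules], dtype=np.int8)
    lens = np.full(n, tmax, dtype=np.int64)
    theta = cohort.theta() if cohort.spec.n_params else None
    rng = _rng.substream(seed, _rng.COHORT_CHOICES)
    c = simulate_choices(cohort.spec, theta, y, cond, lens, rng)

    frames = []
    for i, pid in enumerate(cohort.ids):
        sched = schedules[i]
        rows = []
        for t, trial in enumerate(sched):
            choice = "red" if c[i, t] else "blue"
            rewarded = int(choice == trial.rewarded_stimulus)
            points = (trial.points_red if choice == "red" else trial.points_blue) if rewarded else 0
            rows.append((pid, trial.trial_index, trial.condition, trial.block_index,
                         trial.rewarded_stimulus, trial.points_red, trial.points_blue,
                         choice, rewarded, points))
        frames.append(pd.DataFrame(rows, columns=TRIAL_COLUMNS))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# SDQ questionnaires

N_PROBLEM_ITEMS = 20
N_PROSOCIAL_ITEMS = 5
SDQ_ITEM_COLUMNS = [f"item_{i + 1:02d}" for i in range(N_PROBLEM_ITEMS + N_PROSOCIAL_ITEMS)]


@dataclass(frozen=True)
class SdqRecord:
    """One participant's 25 SDQ item responses (0/1/2 coding).

    Items 1-20 are the four problem subscales (total difficulties,
    0-40); items 21-25 are the prosocial subscale (0-10).
    """

    participant_id: str
    items: Tuple[int, ...]

    def __post_init__(self) -> None:
        score_sdq(self.items)  # validates

    @property
    def total_difficulties(self) -> int:
        return score_sdq(self.items)[0]

    @property
    def prosocial(self) -> int:
        return score_sdq(self.items)[1]


def score_sdq(items: Sequence[int]) -> Tuple[int, int]:
    """Score 25 item responses: (total difficulties 0-40, prosocial 0-10)."""
    items = list(items)
    if len(items) != N_PROBLEM_ITEMS + N_PROSOCIAL_ITEMS:
        raise ValidationError(f"expected 25 item responses, got {len(items)}")
    for i, v in enumerate(items):
        if v not in (0, 1, 2):
            raise ValidationError(f"item {i + 1}: response {v!r} not in {{0, 1, 2}}")
    return int(sum(items[:N_PROBLEM_ITEMS])), int(sum(items[N_PROBLEM_ITEMS:]))


@dataclass(frozen=True)
class SdqEffect:
    """Planted association between a model parameter and prosocial score.

    ``slope`` is the standardized coefficient of the named parameter on
    the latent prosocial propensity; residual noise keeps the latent at
    unit variance when |slope| < 1.
    """

    parameter: str = "alpha_pos_stable"
    slope: float = 0.5
    prosocial_base: float = 0.8   # baseline per-item endorsement propensity
    problem_base: float = 0.2


def generate_sdq(cohort: Cohort, effect: SdqEffect, seed: int) -> pd.DataFrame:
    """Generate SDQ item responses with the planted prosocial association.

    The latent prosocial propensity is ``slope * standardize(parameter)``
    plus Gaussian noise; each prosocial item is Binomial(2, sigmoid of
    shifted latent).  Problem items are exchangeable and independent of
    the model parameters.
    """
    if effect.parameter not in cohort.spec.parameter_names:
        raise ConfigurationError(
            f"parameter: {effect.parameter!r} not in {cohort.spec.model_id}'s "
            f"parameters {list(cohort.spec.parameter_names)}"
        )
    rng = _rng.substream(seed, _rng.SDQ)
    n = len(cohort)
    x = np.array([p[effect.parameter] for p in cohort.params])
    sdx = x.std()
    xs = (x - x.mean()) / sdx if sdx > 0 else np.zeros(n)
    noise_sd = float(np.sqrt(max(0.0, 1.0 - effect.slope**2)))
    latent = effect.slope * xs + noise_sd * rng.standard_normal(n)

    base = np.log(effect.prosocial_base / (1.0 - effect.prosocial_base))
    p_pro = 1.0 / (1.0 + np.exp(-(base + latent)))
    pro_items = rng.binomial(2, p_pro[:, None], size=(n, N_PROSOCIAL_ITEMS))
    prob_items = rng.binomial(2, effect.problem_base, size=(n, N_PROBLEM_ITEMS))

    items = np.concatenate([prob_items, pro_items], axis=1)
    df = pd.DataFrame(items, columns=SDQ_ITEM_COLUMNS)
    df.insert(0, "participant_id", list(cohort.ids))
    df["total_difficulties"] = prob_items.sum(axis=1)
    df["prosocial"] = pro_items.sum(axis=1)
    return df
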