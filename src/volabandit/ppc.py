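"""Posterior-predictive checks, recovery studies and derived measures.

The headline check mirrors the task's learning-curve figure: simulate
each participant on their own schedule using one joint posterior draw of
their parameters, average the choose-red indicator across participants
on each trial (exactly as the empirical data are averaged), smooth with
a centred moving average, and summarize across simulations by the mean
and a highest-density interval.

Derived measures include the learning-rate *adjustment score* — the
volatile-minus-stable learning-rate difference, the task's index of
second-order learning — and parameter/model recovery reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _likelihoods as lk
from . import _rng
from .errors import ValidationError
from .inference import FitSettings, PosteriorDraws, _as_sessions
from .models import AgentParams, get_spec


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Centred moving mean with edge truncation (output length == input).

    Windows are shortened near the edges rather than padded, so the
    first and last points average over (window+1)/2 values.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd count, got {window}")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def hdi(samples: Sequence[float], mass: float = 0.95) -> Tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValidationError(f"hdi needs at least 20 samples, got {n}")
    if not (0.0 < mass < 1.0):
        raise ValidationError(f"mass must lie in (0, 1), got {mass}")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


@dataclass
class PpcCurve:
    """Trial-wise empirical and simulated choice-proportion curves."""

    table: pd.DataFrame  # trial_index, condition, empirical, sim_mean, hdi_lower, hdi_upper
    window: int
    mass: float
    n_sims: int

    def coverage(self) -> float:
        """Fraction of trials whose empirical smoothed mean lies in the HDI."""
        t = self.table
        inside = (t["empirical"] >= t["hdi_lower"]) & (t["empirical"] <= t["hdi_upper"])
        return float(inside.mean())

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        t = self.table
        ax.fill_between(t["trial_index"], t["hdi_lower"], t["hdi_upper"],
                        alpha=0.3, label=f"{int(self.mass * 100)}% HDI (model)")
        ax.plot(t["trial_index"], t["sim_mean"], label="model mean")
        ax.plot(t["trial_index"], t["empirical"], color="k", label="behaviour")
        ax.set_xlabel("trial")
        ax.set_ylabel("p(choose red)")
        ax.set_ylim(0, 1)
        ax.legend(loc="lower left", fontsize=8)
        return ax


def posterior_predictive_curves(draws: PosteriorDraws, dataset, n_sims: int = 200,
                                window: int = 5, mass: float = 0.95,
                                seed: int = 0) -> Union[PpcCurve, Dict[str, PpcCurve]]:
    """Fig-2-style posterior-predictive curves.

    Each simulation draws one posterior sample per participant, replays
    that participant's schedule, averages choose-red across participants
    per trial and smooths.  Returns a single :class:`PpcCurve` when all
    participants share a task order, else a dict keyed by order.
    """
    sd = _as_sessions(dataset)
    if tuple(sd.ids) != tuple(draws.participant_ids):
        raise ValidationError("draws and dataset disagree on participants")
    orders = np.where(sd.cond[:, 0] == 0, "stable_first", "volatile_first")
    unique_orders = list(dict.fromkeys(orders))
    out: Dict[str, PpcCurve] = {}
    for order in unique_orders:
        sel = np.flatnonzero(orders == order)
        out[order] = _ppc_one_order(draws, sd, sel, n_sims, window, mass, seed)
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def _ppc_one_order(draws: PosteriorDraws, sd: lk.SessionData, sel: np.ndarray,
                   n_sims: int, window: int, mass: float, seed: int) -> PpcCurve:
    spec = get_spec(draws.model_id)
    sub = sd.subset(sel)
    if len(set(sub.lens.tolist())) != 1:
        raise ValidationError("PPC requires equal-length sessions within an order")
    T = int(sub.lens[0])
    n = sub.n_participants
    rng = _rng.substream(seed, _rng.PPC)
    sim_curves = np.empty((n_sims, T))
    S = draws.n_draws
    for s in range(n_sims):
        take = rng.integers(0, S, size=n)
        theta = (draws.theta[take, sel, :] if spec.n_params else None)
        c = lk.simulate_choices(spec, theta, sub.y, sub.cond, sub.lens, rng)
        sim_curves[s] = moving_average(c[:, :T].mean(axis=0), window)
    empirical = moving_average(sub.c[:, :T].mean(axis=0), window)
    bounds = np.array([hdi(sim_curves[:, t], mass) for t in range(T)])
    # condition labels per trial (identical across participants in an order)
    cond = np.where(sub.cond[0, :T] == 1, "volatile", "stable")
    table = pd.DataFrame({
        "trial_index": np.arange(T),
        "condition": cond,
        "empirical": empirical,
        "sim_mean": sim_curves.mean(axis=0),
        "hdi_lower": bounds[:, 0],
        "hdi_upper": bounds[:, 1],
    })
    return PpcCurve(table=table, window=window, mass=mass, n_sims=n_sims)


# ---------------------------------------------------------------------------
# adjustment score


@dataclass(frozen=True)
class AdjustmentScore:
    """Volatile-minus-stable learning-rate differences."""

    overall: Union[float, np.ndarray]
    positive: Union[float, np.ndarray]
    negative: Union[float, np.ndarray]


def adjustment_score(params) -> AdjustmentScore:
    """Second-order learning index: mean volatile LR minus mean stable LR.

    Accepts an :class:`AgentParams` with the four-way learning-rate
    split, a mapping with the four cell names, or a DataFrame with those
    columns (returns per-row arrays).
    """
    if isinstance(params, AgentParams):
        source: Mapping = params.values
    elif isinstance(params, (pd.DataFrame, pd.Series, Mapping)):
        source = params
    else:
        raise ValidationError(f"unsupported input type {type(params)!r}")
    try:
        ps, ns = source["alpha_pos_stable"], source["alpha_neg_stable"]
        pv, nv = source["alpha_pos_volatile"], source["alpha_neg_volatile"]
    except KeyError as exc:
        raise ValidationError(
            "adjustment_score requires the four-way learning-rate split "
            f"(missing {exc})") from exc
    pos = np.asarray(pv) - np.asarray(ps)
    neg = np.asarray(nv) - np.asarray(ns)
    overall = (np.asarray(pv) + np.asarray(nv)) / 2.0 - (np.asarray(ps) + np.asarray(ns)) / 2.0
    if np.ndim(overall) == 0:
        return AdjustmentScore(float(overall), float(pos), float(neg))
    return AdjustmentScore(overall, pos, neg)


# ---------------------------------------------------------------------------
# recovery


@dataclass
class RecoveryReport:
    """Parameter-recovery metrics (and optional model-recovery counts)."""

    per_parameter: pd.DataFrame  # parameter, correlation, mean_error, rmse
    confusion: Optional[pd.DataFrame] = None


def recovery_report(true_params: pd.DataFrame, fitted,
                    confusion: Optional[pd.DataFrame] = None) -> RecoveryReport:
    """Compare true participant parameters against posterior means.

    ``true_params``: DataFrame with participant_id plus one column per
    parameter.  ``fitted``: PosteriorDraws or a results object.
    """
    draws: PosteriorDraws = getattr(fitted, "draws", fitted)
    est = draws.participant_posterior_mean().set_index("participant_id")
    true = true_params.set_index("participant_id")
    if set(est.index) != set(true.index):
        raise ValidationError("participant ids of true and fitted parameters differ")
    true = true.loc[est.index]
    rows = []
    for name in draws.parameter_names:
        t = true[name].to_numpy(dtype=float)
        e = est[name].to_numpy(dtype=float)
        err = e - t
        corr = float(np.corrcoef(t, e)[0, 1]) if len(t) > 1 else np.nan
        rows.append({"parameter": name, "correlation": corr,
                     "mean_error": float(err.mean()),
                     "rmse": float(np.sqrt((err**2).mean()))})
    return RecoveryReport(per_parameter=pd.DataFrame(rows), confusion=confusion)


# ---------------------------------------------------------------------------
# reusable study drivers (shared by the test-suite and acceptance script)


def parameter_recovery_study(n: int = 40, seeds: Sequence[int] = (0, 1, 2),
                             settings: Optional[FitSettings] = None) -> pd.DataFrame:
    """Simulate reference-regime M11 cohorts, fit, and report recovery.

    Returns one row per (seed, parameter) with the true-vs-posterior-mean
    correlation, bias and RMSE.
    """
    from .cohort import default_group_hyper, sample_cohort, simulate_cohort
    from .inference import HierarchicalBanditModel
    from .task import TaskConfig

    spec = get_spec("M11")
    hyper = default_group_hyper(spec)
    config = TaskConfig()
    if settings is None:
        settings = FitSettings(algorithm="map_laplace", n_chains=2, n_samples=250)
    rows = []
    for seed in seeds:
        cohort = sample_cohort(hyper, n, spec, seed=seed)
        trials = simulate_cohort(cohort, config, seed=seed)
        res = HierarchicalBanditModel(trials, spec).fit(settings.replace(seed=seed))
        report = recovery_report(cohort.to_frame(), res)
        for _, r in report.per_parameter.iterrows():
            rows.append({"seed": seed, **r.to_dict()})
    return pd.DataFrame(rows)


def model_recovery_study(candidates: Sequence[str] = ("M0", "M2", "M4", "M11"),
                         generating: str = "M11", n: int = 30,
                         seeds: Sequence[int] = tuple(range(10)),
                         settings: Optional[FitSettings] = None,
                         K: int = 5, holdout_draws: int = 100) -> pd.DataFrame:
    """Which model wins 5-fold CV on cohorts generated from ``generating``.

    Returns one row per seed with each candidate's elpd and the winner.
    """
    from .cohort import default_group_hyper, sample_cohort, simulate_cohort
    from .inference import HierarchicalBanditModel
    from .selection import kfold_cv
    from .task import TaskConfig

    gen_spec = get_spec(generating)
    hyper = default_group_hyper(gen_spec)
    config = TaskConfig()
    if settings is None:
        settings = FitSettings(algorithm="map_laplace", n_chains=2, n_samples=200,
                               maxiter=600)
    rows = []
    for seed in seeds:
        cohort = sample_cohort(hyper, n, gen_spec, seed=seed)
        trials = simulate_cohort(cohort, config, seed=seed)
        sd = _as_sessions(trials)
        row: Dict[str, object] = {"seed": seed}
        for mid in candidates:
            kf = kfold_cv(get_spec(mid), sd, K=K, settings=settings, seed=seed,
                          holdout_draws=holdout_draws)
            row[f"elpd_{mid}"] = kf.elpd
        elpds = {mid: row[f"elpd_{mid}"] for mid in candidates}
        row["winner"] = max(elpds, key=elpds.get)
        rows.append(row)
    return pd.DataFrame(rows)


def model_confusion(study: pd.DataFrame, candidates: Sequence[str]) -> pd.DataFrame:
    """Winner counts from a model-recovery study table."""
    counts = study["winner"].value_counts()
    return pd.DataFrame({"model_id": list(candidates),
                         "wins": [int(counts.get(m, 0)) for m in candidates]})
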