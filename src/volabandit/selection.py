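"""Model comparison: WAIC, K-fold cross-validation and evidence labels.

WAIC is computed on the deviance scale with the participant-session as
the pointwise unit (matching the participant-level grain of the K-fold
scheme, so the two scales are comparable); a trial-level variant is
available behind the ``unit`` flag.  K-fold CV partitions participants,
refits on the retained participants and scores each held-out participant
by the log of the posterior-averaged likelihood, integrating over the
held-out individual's parameters as a new draw from the group-level
posterior — the honest hierarchical predictive.

Evidence differences on the 5-fold CV scale are labelled
weak [0, 2], positive (2, 6], strong (6, 10], very strong (10, inf):
the boundary values 2, 6, 10 belong to the lower category.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _likelihoods as lk
from . import _rng
from .errors import ValidationError
from .inference import (FitSettings, HierarchicalBanditModel,
                        HierarchicalBanditResults, PosteriorDraws, PriorConfig,
                        _as_sessions)
from .models import ModelSpec, get_spec

EVIDENCE_CATEGORIES = ("weak", "positive", "strong", "very_strong")


@dataclass(frozen=True)
class WaicResult:
    """WAIC on the deviance scale with its components."""

    waic: float
    se: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # per-unit -2*(lppd_i - p_i)

    @property
    def elpd(self) -> float:
        return self.lppd - self.p_waic


def compute_waic(loglik: np.ndarray, unit: str = "participant") -> WaicResult:
    """WAIC from a pointwise log-likelihood array.

    ``loglik`` has shape (draw, participant, trial) or (draw, unit); with
    the default participant unit trials are summed within participant
    first.  Requires at least two draws.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.sum(axis=2) if unit == "participant" else ll.reshape(ll.shape[0], -1)
    if ll.ndim != 2:
        raise ValidationError(f"loglik must be 2- or 3-dimensional, got {ll.ndim}")
    S = ll.shape[0]
    if S < 2:
        raise ValidationError("WAIC needs at least two draws (variance undefined)")
    if not np.all(np.isfinite(ll)):
        raise ValidationError("loglik contains non-finite entries")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    n_units = ll.shape[1]
    se = float(np.sqrt(n_units * waic_i.var(ddof=1))) if n_units > 1 else 0.0
    return WaicResult(waic=float(waic_i.sum()), se=se, lppd=float(lppd_i.sum()),
                      p_waic=float(p_i.sum()), pointwise=waic_i)


def classify_evidence(delta: float) -> str:
    """Categorical evidence label for a nonnegative CV difference."""
    if delta < 0:
        raise ValidationError(f"delta must be nonnegative, got {delta!r}")
    if delta <= 2:
        return "weak"
    if delta <= 6:
        return "positive"
    if delta <= 10:
        return "strong"
    return "very_strong"


@dataclass
class KfoldResult:
    """Participant-level K-fold cross-validation detail."""

    elpd: float
    fold_elpds: np.ndarray
    per_participant: pd.Series
    assignments: Dict[str, int]


def kfold_cv(spec: ModelSpec, dataset, K: int = 5,
             settings: FitSettings = FitSettings(), seed: int = 0,
             holdout_draws: int = 200, priors: PriorConfig = PriorConfig()) -> KfoldResult:
    """K-fold CV over participants for one model.

    Folds are a seeded partition with sizes differing by at most one.
    Each held-out participant is scored as log (1/S) sum_s p(y | z_s)
    with z_s a fresh participant-level draw from the group posterior of
    the training fit.
    """
    sd = _as_sessions(dataset)
    n = sd.n_participants
    if K < 2:
        raise ValidationError("K must be at least 2")
    if n < K:
        raise ValidationError(f"need at least K={K} participants, got {n}")
    rng = _rng.substream(seed, _rng.KFOLD)
    perm = rng.permutation(n)
    folds = np.array_split(perm, K)

    per_part = pd.Series(index=list(sd.ids), dtype=float)
    assignments = {}
    fold_elpds = np.zeros(K)
    for f, hold in enumerate(folds):
        hold = np.sort(hold)
        for i in hold:
            assignments[sd.ids[i]] = f
        hold_sd = sd.subset(hold)
        if spec.n_params == 0:
            elpd_j = hold_sd.lens * np.log(0.5)
        else:
            train = np.sort(np.setdiff1d(perm, hold))
            train_sd = sd.subset(train)
            fold_seed = _rng.child_seed(seed, _rng.KFOLD, f + 1)
            fit_settings = settings.replace(seed=fold_seed)
            res = HierarchicalBanditModel(train_sd, spec, priors).fit(fit_settings)
            elpd_j = _score_holdout(spec, res.draws, hold_sd, holdout_draws, fold_seed)
        fold_elpds[f] = float(np.sum(elpd_j))
        for i, j in enumerate(hold):
            per_part[sd.ids[j]] = float(elpd_j[i])
    return KfoldResult(elpd=float(fold_elpds.sum()), fold_elpds=fold_elpds,
                       per_participant=per_part, assignments=assignments)


def _score_holdout(spec: ModelSpec, draws: PosteriorDraws, hold_sd: lk.SessionData,
                   holdout_draws: int, seed: int) -> np.ndarray:
    """New-participant predictive log score, one value per held-out id."""
    S_all = draws.n_draws
    S = min(holdout_draws, S_all)
    idx = np.linspace(0, S_all - 1, S).astype(int)
    mu = draws.mu[idx]
    sigma = draws.sigma[idx]
    rng = np.random.default_rng(seed)
    m = hold_sd.n_participants
    K = spec.n_params
    # one fresh z per (posterior draw, held-out participant)
    z = mu[:, None, :] + sigma[:, None, :] * rng.standard_normal((S, m, K))
    theta = lk.constrain(z, spec.parameter_names)
    # batch the (draw x participant) grid through the likelihood kernel
    big = lk.SessionData(
        ids=tuple(f"{pid}@{s}" for s in range(S) for pid in hold_sd.ids),
        y=np.tile(hold_sd.y, (S, 1)),
        c=np.tile(hold_sd.c, (S, 1)),
        cond=np.tile(hold_sd.cond, (S, 1)),
        lens=np.tile(hold_sd.lens, S),
    )
    ll, _ = lk.loglik_grad(spec, big, theta.reshape(S * m, K))
    ll = ll.reshape(S, m)
    return logsumexp(ll, axis=0) - np.log(S)


@dataclass
class ComparisonResult:
    """Comparison table over a set of fitted models.

    ``table`` columns: model_id, n_params, waic, se_waic, p_waic,
    elpd_kfold, delta_vs_best, evidence — sorted by 5-fold elpd with
    ties broken by parameter count then model_id.
    """

    table: pd.DataFrame
    kfold: Dict[str, KfoldResult]
    scale: str = "elpd"

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model_id"])


def compare_models(fits: Sequence[Union[HierarchicalBanditResults, PosteriorDraws]],
                   dataset, settings: Optional[FitSettings] = None, K: int = 5,
                   seed: int = 0, holdout_draws: int = 200,
                   scale: str = "elpd",
                   priors: PriorConfig = PriorConfig()) -> ComparisonResult:
    """Rank models by 5-fold CV elpd with WAIC reported alongside.

    ``fits`` are full-data fits (used for WAIC); the cross-validation
    refits each model per fold.  ``scale`` controls whether evidence
    categories are applied to elpd differences directly ('elpd') or to
    deviance-scaled differences ('deviance', x2).
    """
    sd = _as_sessions(dataset)
    rows = []
    kfolds: Dict[str, KfoldResult] = {}
    for item in fits:
        draws = item.draws if isinstance(item, HierarchicalBanditResults) else item
        if tuple(draws.participant_ids) != tuple(sd.ids):
            raise ValidationError(
                f"{draws.model_id}: fit participants do not match the dataset")
        spec = get_spec(draws.model_id)
        if settings is None:
            settings = (item.settings if isinstance(item, HierarchicalBanditResults)
                        else FitSettings())
        from .inference import pointwise_loglik

        w = compute_waic(pointwise_loglik(draws, sd))
        kf = kfold_cv(spec, sd, K=K, settings=settings, seed=seed,
                      holdout_draws=holdout_draws, priors=priors)
        kfolds[spec.model_id] = kf
        rows.append({"model_id": spec.model_id, "n_params": spec.n_params,
                     "waic": w.waic, "se_waic": w.se, "p_waic": w.p_waic,
                     "elpd_kfold": kf.elpd})
    table = pd.DataFrame(rows).sort_values(
        by=["elpd_kfold", "n_params", "model_id"],
        ascending=[False, True, True]).reset_index(drop=True)
    best = table["elpd_kfold"].iloc[0]
    delta = best - table["elpd_kfold"]
    if scale == "deviance":
        delta = 2.0 * delta
    table["delta_vs_best"] = delta
    table["evidence"] = [classify_evidence(max(0.0, d)) for d in delta]
    return ComparisonResult(table=table, kfold=kfolds, scale=scale)
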