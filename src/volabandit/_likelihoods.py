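"""Vectorized likelihoods, gradients and simulators for the model ladder.

The hierarchical fitter evaluates the joint density thousands of times,
so the per-trial recursions are compiled with numba over a packed
(participant x trial) representation.  The pure-Python reference path
lives in :mod:`volabandit.models` (``session_loglik``); the two are
cross-checked in the test suite.

Gradients for the delta-rule family propagate sensitivities of the
tracked value through the update recursion (the dependence of the
learning-rate *selection* on the value is piecewise constant and is
ignored at the measure-zero kink, as is standard).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .errors import ValidationError
from .models import LR_CELLS, ModelSpec


# ---------------------------------------------------------------------------
# packed sessions


@dataclass(frozen=True)
class SessionData:
    """Choice data packed as (participant x trial) integer arrays.

    ``y``: rewarded stimulus is red; ``c``: chose red; ``cond``: volatile
    flag.  Ragged sessions are padded and masked via ``lens``.
    """

    ids: Tuple[str, ...]
    y: np.ndarray
    c: np.ndarray
    cond: np.ndarray
    lens: np.ndarray

    @property
    def n_participants(self) -> int:
        return len(self.ids)

    @property
    def n_trials_total(self) -> int:
        return int(self.lens.sum())

    def subset(self, indices) -> "SessionData":
        indices = np.asarray(indices)
        return SessionData(
            ids=tuple(self.ids[i] for i in indices),
            y=self.y[indices],
            c=self.c[indices],
            cond=self.cond[indices],
            lens=self.lens[indices],
        )


def pack_sessions(df: pd.DataFrame) -> SessionData:
    """Pack a validated trial DataFrame into SessionData.

    Participants are ordered by first appearance; trials by trial_index.
    Every trial must carry a choice.
    """
    if df["choice"].isna().any() or (df["choice"] == "").any():
        raise ValidationError("dataset contains trials without a recorded choice")
    ids = list(dict.fromkeys(df["participant_id"].astype(str)))
    groups = {pid: g.sort_values("trial_index") for pid, g in df.groupby(df["participant_id"].astype(str))}
    lens = np.array([len(groups[pid]) for pid in ids], dtype=np.int64)
    if (lens < 1).any():
        raise ValidationError("every participant needs at least one trial")
    tmax = int(lens.max())
    n = len(ids)
    y = np.zeros((n, tmax), dtype=np.int8)
    c = np.zeros((n, tmax), dtype=np.int8)
    cond = np.zeros((n, tmax), dtype=np.int8)
    for i, pid in enumerate(ids):
        g = groups[pid]
        t = len(g)
        y[i, :t] = (g["rewarded_stimulus"].to_numpy() == "red").astype(np.int8)
        c[i, :t] = (g["choice"].to_numpy() == "red").astype(np.int8)
        cond[i, :t] = (g["condition"].to_numpy() == "volatile").astype(np.int8)
    return SessionData(ids=tuple(ids), y=y, c=c, cond=cond, lens=lens)


# ---------------------------------------------------------------------------
# constraining transforms


def transform_kind(name: str) -> str:
    return "log" if name.startswith("temperature") else "logit"


def constrain(z: np.ndarray, names) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    for k, name in enumerate(names):
        if transform_kind(name) == "log":
            out[..., k] = np.exp(z[..., k])
        else:
            out[..., k] = 1.0 / (1.0 + np.exp(-z[..., k]))
    return out


def unconstrain(x: np.ndarray, names) -> np.ndarray:
    out = np.empty_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    for k, name in enumerate(names):
        if transform_kind(name) == "log":
            out[..., k] = np.log(x[..., k])
        else:
            out[..., k] = np.log(x[..., k] / (1.0 - x[..., k]))
    return out


def dconstrain_dz(constrained: np.ndarray, names) -> np.ndarray:
    """d(constrained)/d(unconstrained), evaluated at the constrained value."""
    out = np.empty_like(constrained)
    for k, name in enumerate(names):
        if transform_kind(name) == "log":
            out[..., k] = constrained[..., k]
        else:
            a = constrained[..., k]
            out[..., k] = a * (1.0 - a)
    return out


# ---------------------------------------------------------------------------
# delta-rule kernels


@njit(cache=True)
def _delta_ll_grad(y, c, cond, lens, alphas, taus):  # pragma: no cover - compiled
    n = y.shape[0]
    ll = np.zeros(n)
    ga = np.zeros((n, 4))
    gt = np.zeros((n, 2))
    for i in range(n):
        v = 0.5
        s = np.zeros(4)
        for t in range(lens[i]):
            cd = cond[i, t]
            tau = taus[i, cd]
            x = (2.0 * v - 1.0) / tau
            ci = c[i, t]
            if ci == 1:
                ll[i] += -np.logaddexp(0.0, -x)
            else:
                ll[i] += -np.logaddexp(0.0, x)
            p = 1.0 / (1.0 + np.exp(-x))
            resid = ci - p
            dll_dv = resid * 2.0 / tau
            gt[i, cd] += resid * (-(2.0 * v - 1.0) / (tau * tau))
            for k in range(4):
                ga[i, k] += dll_dv * s[k]
            yi = y[i, t]
            r = 1.0 if ci == yi else 0.0
            vc = v if ci == 1 else 1.0 - v
            delta = r - vc
            if delta >= 0.0:
                cell = cd * 2
            else:
                cell = cd * 2 + 1
            a = alphas[i, cell]
            for k in range(4):
                s[k] = (1.0 - a) * s[k]
            s[cell] += yi - v
            v = v + a * (yi - v)
    return ll, ga, gt


@njit(cache=True)
def _delta_pointwise(y, c, cond, lens, alphas, taus):  # pragma: no cover - compiled
    n, tmax = y.shape
    llmat = np.zeros((n, tmax))
    for i in range(n):
        v = 0.5
        for t in range(lens[i]):
            cd = cond[i, t]
            tau = taus[i, cd]
            x = (2.0 * v - 1.0) / tau
            ci = c[i, t]
            if ci == 1:
                llmat[i, t] = -np.logaddexp(0.0, -x)
            else:
                llmat[i, t] = -np.logaddexp(0.0, x)
            yi = y[i, t]
            r = 1.0 if ci == yi else 0.0
            vc = v if ci == 1 else 1.0 - v
            delta = r - vc
            if delta >= 0.0:
                cell = cd * 2
            else:
                cell = cd * 2 + 1
            a = alphas[i, cell]
            v = v + a * (yi - v)
    return llmat


@njit(cache=True)
def _delta_simulate(y, cond, lens, alphas, taus, u):  # pragma: no cover - compiled
    n, tmax = y.shape
    c = np.zeros((n, tmax), dtype=np.int8)
    for i in range(n):
        v = 0.5
        for t in range(lens[i]):
            cd = cond[i, t]
            tau = taus[i, cd]
            x = (2.0 * v - 1.0) / tau
            p = 1.0 / (1.0 + np.exp(-x))
            ci = 1 if u[i, t] < p else 0
            c[i, t] = ci
            yi = y[i, t]
            r = 1.0 if ci == yi else 0.0
            vc = v if ci == 1 else 1.0 - v
            delta = r - vc
            if delta >= 0.0:
                cell = cd * 2
            else:
                cell = cd * 2 + 1
            a = alphas[i, cell]
            v = v + a * (yi - v)
    return c


# ---------------------------------------------------------------------------
# parameter-cell mappings


def _alpha_map(spec: ModelSpec) -> List[Optional[int]]:
    """Parameter index feeding each of the four LR cells (None => fixed 1)."""
    names = list(spec.parameter_names)
    if spec.lr_split == "fixed_one":
        return [None, None, None, None]
    # cell order must match LR_CELLS: ps, ns, pv, nv
    order = [("stable", "positive"), ("stable", "negative"),
             ("volatile", "positive"), ("volatile", "negative")]
    return [names.index(spec.alpha_name(cond, sign)) for cond, sign in order]


def _tau_map(spec: ModelSpec) -> List[int]:
    names = list(spec.parameter_names)
    return [names.index(spec.temperature_name("stable")),
            names.index(spec.temperature_name("volatile"))]


def _expand_delta(spec: ModelSpec, theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Map constrained parameters (n, K) to per-cell alphas (n,4), taus (n,2)."""
    n = theta.shape[0]
    amap, tmap = _alpha_map(spec), _tau_map(spec)
    alphas = np.ones((n, 4))
    for cell, j in enumerate(amap):
        if j is not None:
            alphas[:, cell] = theta[:, j]
    taus = np.column_stack([theta[:, tmap[0]], theta[:, tmap[1]]])
    return alphas, taus


def _collapse_delta_grad(spec: ModelSpec, ga: np.ndarray, gt: np.ndarray) -> np.ndarray:
    n = ga.shape[0]
    g = np.zeros((n, spec.n_params))
    for cell, j in enumerate(_alpha_map(spec)):
        if j is not None:
            g[:, j] += ga[:, cell]
    tmap = _tau_map(spec)
    if tmap[0] == tmap[1]:
        g[:, tmap[0]] += gt[:, 0] + gt[:, 1]
    else:
        g[:, tmap[0]] += gt[:, 0]
        g[:, tmap[1]] += gt[:, 1]
    return g


# ---------------------------------------------------------------------------
# non-recursive families (numpy)


def _wsls_terms(sd: SessionData):
    c, y, lens = sd.c, sd.y, sd.lens
    n, tmax = c.shape
    mask = np.arange(tmax)[None, :] < lens[:, None]
    r = (c == y).astype(float)
    prev_r = np.zeros_like(r)
    prev_r[:, 1:] = r[:, :-1]
    repeated = np.zeros_like(r)
    repeated[:, 1:] = (c[:, 1:] == c[:, :-1]).astype(float)
    first = np.zeros((n, tmax), dtype=bool)
    first[:, 0] = True
    later = mask & ~first
    return mask, first, later, prev_r, repeated


def _wsls_pointwise(sd: SessionData, theta: np.ndarray) -> np.ndarray:
    sw = theta[:, 0][:, None]
    sl = theta[:, 1][:, None]
    mask, first, later, prev_r, repeated = _wsls_terms(sd)
    p_rep = np.where(prev_r == 1.0, sw, 1.0 - sl)
    ll = np.where(repeated == 1.0, np.log(p_rep), np.log1p(-p_rep))
    out = np.zeros_like(ll)
    out[first] = np.log(0.5)
    out[later] = ll[later]
    return out


def _wsls_ll_grad(sd: SessionData, theta: np.ndarray):
    sw = theta[:, 0][:, None]
    sl = theta[:, 1][:, None]
    mask, first, later, prev_r, repeated = _wsls_terms(sd)
    p_rep = np.where(prev_r == 1.0, sw, 1.0 - sl)
    dll_dprep = np.where(repeated == 1.0, 1.0 / p_rep, -1.0 / (1.0 - p_rep))
    dll_dprep = np.where(later, dll_dprep, 0.0)
    g_sw = np.where(prev_r == 1.0, dll_dprep, 0.0).sum(axis=1)
    g_sl = np.where(prev_r == 0.0, -dll_dprep, 0.0).sum(axis=1)
    ll = _wsls_pointwise(sd, theta).sum(axis=1)
    return ll, np.column_stack([g_sw, g_sl])


def _null_pointwise(sd: SessionData, theta: Optional[np.ndarray]) -> np.ndarray:
    n, tmax = sd.c.shape
    mask = np.arange(tmax)[None, :] < sd.lens[:, None]
    if theta is None or theta.shape[1] == 0:
        return np.where(mask, np.log(0.5), 0.0)
    b = theta[:, 0][:, None]
    ll = np.where(sd.c == 1, np.log(b), np.log1p(-b))
    return np.where(mask, ll, 0.0)


def _null_ll_grad(sd: SessionData, theta: np.ndarray):
    b = theta[:, 0][:, None]
    n, tmax = sd.c.shape
    mask = np.arange(tmax)[None, :] < sd.lens[:, None]
    g = np.where(sd.c == 1, 1.0 / b, -1.0 / (1.0 - b))
    g = np.where(mask, g, 0.0).sum(axis=1)
    ll = _null_pointwise(sd, theta).sum(axis=1)
    return ll, g[:, None]


# ---------------------------------------------------------------------------
# public dispatch


def loglik_grad(spec: ModelSpec, sd: SessionData, theta: np.ndarray):
    """Per-participant log-likelihood and gradient wrt constrained params.

    ``theta``: constrained parameter matrix (n_participants, n_params).
    """
    if spec.family == "delta_rule":
        alphas, taus = _expand_delta(spec, theta)
        ll, ga, gt = _delta_ll_grad(sd.y, sd.c, sd.cond, sd.lens, alphas, taus)
        return ll, _collapse_delta_grad(spec, ga, gt)
    if spec.family == "wsls":
        return _wsls_ll_grad(sd, theta)
    if spec.n_params == 0:
        ll = _null_pointwise(sd, None).sum(axis=1)
        return ll, np.zeros((sd.n_participants, 0))
    return _null_ll_grad(sd, theta)


def pointwise(spec: ModelSpec, sd: SessionData, theta: Optional[np.ndarray]) -> np.ndarray:
    """Per-trial log-likelihood matrix (n_participants, t_max)."""
    if spec.family == "delta_rule":
        alphas, taus = _expand_delta(spec, theta)
        return _delta_pointwise(sd.y, sd.c, sd.cond, sd.lens, alphas, taus)
    if spec.family == "wsls":
        return _wsls_pointwise(sd, theta)
    return _null_pointwise(sd, theta)


def simulate_choices(spec: ModelSpec, theta: Optional[np.ndarray], y: np.ndarray,
                     cond: np.ndarray, lens: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Simulate choose-red indicators for a batch of agents on schedules.

    ``y``/``cond``: (n, t_max) schedule arrays; one agent per row with
    its own parameter vector.
    """
    n, tmax = y.shape
    u = rng.random((n, tmax))
    if spec.family == "delta_rule":
        alphas, taus = _expand_delta(spec, theta)
        return _delta_simulate(y.astype(np.int8), cond.astype(np.int8),
                               lens.astype(np.int64), alphas, taus, u)
    c = np.zeros((n, tmax), dtype=np.int8)
    if spec.family == "null":
        b = 0.5 if (theta is None or theta.shape[1] == 0) else theta[:, 0][:, None]
        c[:] = (u < b).astype(np.int8)
        return c
    # wsls
    sw, sl = theta[:, 0], theta[:, 1]
    prev_c = np.zeros(n, dtype=np.int8)
    prev_r = np.zeros(n, dtype=np.int8)
    for t in range(tmax):
        if t == 0:
            p_red = np.full(n, 0.5)
        else:
            p_rep = np.where(prev_r == 1, sw, 1.0 - sl)
            p_red = np.where(prev_c == 1, p_rep, 1.0 - p_rep)
        ct = (u[:, t] < p_red).astype(np.int8)
        c[:, t] = ct
        prev_c = ct
        prev_r = (ct == y[:, t]).astype(np.int8)
    return c
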