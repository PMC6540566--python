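"""Likelihood, score and information for the grouped failure-time model.

The model is a discrete-interval proportional-hazards model: event or
censoring times are observed only up to membership in one of ``r``
pre-specified intervals ``[t_{j-1}, t_j)`` with ``t_0 = 0`` and
``t_r = inf``.  A sample is described by the interval index ``k`` (1-based)
and an event flag ``delta``; ``(k, delta=1)`` means the event occurred in
interval ``k`` while ``(k, delta=0)`` means right-censoring at ``t_{k-1}``.

With per-interval baseline survival probabilities ``alpha_j`` (probability
that a baseline subject at risk at ``t_{j-1}`` survives interval ``j``) and
log relative risk ``m_i = x_i*beta + z_i . theta``, the per-sample likelihood
is

    L_i = (1 - alpha_{k_i}^{w_i})^{delta_i} * prod_{j < k_i} alpha_j^{w_i},

where ``w_i = exp(m_i)``.  Internally the baseline block is handled on the
unconstrained complementary-log-log scale ``zeta_j = log(-log alpha_j)``,
which removes the box constraint ``alpha_j in (0, 1)``.

All heavy computations are vectorised over samples; interval-indexed sums
use bincount-based suffix sums so cost is ``O(n + r)`` per derivative block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GroupedDataset",
    "ModelParams",
    "ScoreBundle",
    "alpha_to_zeta",
    "zeta_to_alpha",
    "log_likelihood",
    "per_sample_loglik",
    "score_and_information",
]


def alpha_to_zeta(alpha: np.ndarray) -> np.ndarray:
    """Map interval survival probabilities to the unconstrained cloglog scale."""
    alpha = np.asarray(alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(-np.log(alpha))


def zeta_to_alpha(zeta: np.ndarray) -> np.ndarray:
    return np.exp(-np.exp(np.asarray(zeta, dtype=float)))


@dataclass
class GroupedDataset:
    """Grouped survival outcomes plus baseline covariates for ``n`` samples.

    Parameters
    ----------
    k : (n,) int array
        1-based interval index of the grouped outcome.
    delta : (n,) int array
        Event indicator; 1 = event in interval ``k``, 0 = right-censored
        at ``t_{k-1}``.  ``(k=1, delta=0)`` is legal and denotes
        uninformative censoring at time 0 (likelihood contribution 1).
    covariates : (n, q) float array
        Baseline covariates; ``q`` may be 0.  No intercept column should be
        included: the baseline is absorbed by the ``alpha_j``.
    sample_ids : sequence of str, optional
    r : int, optional
        Dataset-wide number of intervals; inferred as ``max(k)`` if omitted.
    """

    k: np.ndarray
    delta: np.ndarray
    covariates: np.ndarray
    sample_ids: Optional[np.ndarray] = None
    r: Optional[int] = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.delta = np.asarray(self.delta, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.k.shape[0]:
            if self.covariates.size == 0:
                self.covariates = np.empty((self.k.shape[0], 0))
            else:
                raise ValueError(
                    f"covariate rows ({self.covariates.shape[0]}) != "
                    f"number of outcomes ({self.k.shape[0]})"
                )
        n = self.k.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one sample")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape[0] != n:
                raise ValueError("sample_ids length mismatch")
        if self.r is None:
            self.r = int(self.k.max())
        if not np.all((self.k >= 1) & (self.k <= self.r)):
            raise ValueError(f"interval indices must lie in 1..r={self.r}")
        if not np.all((self.delta == 0) | (self.delta == 1)):
            raise ValueError("event indicator must be 0 or 1")
        if not np.all(np.isfinite(self.covariates)[~np.isnan(self.covariates)]):
            raise ValueError("covariates must be finite or NaN (missing)")

    @property
    def n(self) -> int:
        return int(self.k.shape[0])

    @property
    def q(self) -> int:
        return int(self.covariates.shape[1])

    def subset(self, mask: np.ndarray) -> "GroupedDataset":
        return GroupedDataset(
            self.k[mask],
            self.delta[mask],
            self.covariates[mask],
            self.sample_ids[mask],
            r=self.r,
        )


@dataclass
class ModelParams:
    """Parameter point ``(beta, theta, alpha)`` of the grouped model."""

    beta: float
    theta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.beta = float(self.beta)
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        ok = np.isnan(self.alpha) | ((self.alpha > 0) | (self.alpha == 0)) & (
            self.alpha <= 1
        )
        if not np.all(ok):
            raise ValueError("alpha entries must lie in [0, 1] (NaN = undefined)")
        if not np.isfinite(self.beta) or not np.all(np.isfinite(self.theta)):
            raise ValueError("beta/theta must be finite")

    @property
    def zeta(self) -> np.ndarray:
        return alpha_to_zeta(self.alpha)


@dataclass
class ScoreBundle:
    """Score vector and averaged information blocks at a parameter point.

    ``score`` is ordered ``(beta, theta, baseline-block)`` with the baseline
    block on the zeta (cloglog) scale; entries for intervals fixed at the
    boundary (``alpha_j`` equal to 0 or 1) or without information are 0 and
    excluded from the free mask.  Information blocks are averaged negative
    second derivatives of the total log-likelihood (divided by ``n``).
    """

    score: np.ndarray  # (1 + q + r,)
    per_sample_scores: np.ndarray  # (n, 1 + q + r)
    info_bb: float
    info_bn: np.ndarray  # (q + r,)
    info_nn: np.ndarray  # (q + r, q + r)
    n: int
    eta_free: np.ndarray  # (q + r,) bool — free nuisance directions
    flags: dict = field(default_factory=dict)


def _log_alpha(alpha: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(alpha)


def _linear_predictor(data: GroupedDataset, x, params: ModelParams) -> np.ndarray:
    m = np.zeros(data.n)
    if x is not None:
        m = m + np.asarray(x, dtype=float) * params.beta
    if data.q:
        if params.theta.shape[0] != data.q:
            raise ValueError("theta length does not match covariate count")
        m = m + data.covariates @ params.theta
    return m


def per_sample_loglik(data: GroupedDataset, x, params: ModelParams) -> np.ndarray:
    """Per-sample log-likelihood contributions (each <= 0).

    An event recorded in an interval with ``alpha_j = 1`` has likelihood 0
    and is reported as ``-inf`` rather than raising.
    """
    if params.alpha.shape[0] < data.r:
        raise ValueError("alpha shorter than number of intervals")
    if x is not None:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("x must be finite")
    L = np.nan_to_num(_log_alpha(params.alpha), nan=0.0)  # undefined intervals inert
    m = _linear_predictor(data, x, params)
    w = np.exp(m)
    cumL = np.concatenate([[0.0], np.cumsum(L)])
    A = cumL[data.k - 1]  # sum_{j < k} log alpha_j
    ll = w * A
    ev = data.delta.astype(bool)
    u = w[ev] * L[data.k[ev] - 1]
    with np.errstate(divide="ignore"):
        ll[ev] += np.log(-np.expm1(u))
    return ll


def log_likelihood(data: GroupedDataset, x, params: ModelParams) -> float:
    """Total grouped-model log-likelihood ``sum_i log L_i``."""
    return float(np.sum(per_sample_loglik(data, x, params)))


def _suffix_sums(kk: np.ndarray, weights: np.ndarray, r: int) -> np.ndarray:
    """``out[j] = sum of weights over samples with kk > j`` (kk 0-based)."""
    byk = np.bincount(kk, weights=weights, minlength=r)
    return weights.sum() - np.cumsum(byk)


def _event_sums(kk_ev: np.ndarray, weights: np.ndarray, r: int) -> np.ndarray:
    return np.bincount(kk_ev, weights=weights, minlength=r)


def derivative_pieces(data: GroupedDataset, x, params: ModelParams):
    """Per-sample ingredients of the score and Hessian.

    Returns a dict with ``w`` (relative risks), ``a = d l_i / d m_i``,
    ``b = d^2 l_i / d m_i^2``, the event-only curvature ``cquad`` and slope
    ``epu`` scattered to full length, and the safe log-alpha vector.
    """
    L = np.nan_to_num(_log_alpha(params.alpha), nan=0.0)
    m = _linear_predictor(data, x, params)
    w = np.exp(m)
    cumL = np.concatenate([[0.0], np.cumsum(L)])
    A = cumL[data.k - 1]
    ev = data.delta.astype(bool)
    kk = data.k - 1
    u = w[ev] * L[kk[ev]]
    boundary = u == 0  # event in an interval with alpha = 1: degenerate
    # u = -inf (event in an interval with alpha = 0): the event factor is 1,
    # contributing nothing to score or curvature
    dead = np.isneginf(u)
    u_safe = np.where(boundary | dead, -1.0, u)
    with np.errstate(divide="ignore", over="ignore"):
        g = 1.0 / np.expm1(-u_safe)
    epu_ev = -g * u_safe  # E'(u)·u >= 0
    cq_ev = -g * (1.0 + g) * u_safe * u_safe + epu_ev
    epu_ev[boundary | dead] = 0.0
    cq_ev[boundary | dead] = 0.0
    epu = np.zeros(data.n)
    cquad = np.zeros(data.n)
    epu[ev] = epu_ev
    cquad[ev] = cq_ev
    wA = w * A
    a = wA + epu
    b = wA + cquad
    return {
        "L": L,
        "w": w,
        "a": a,
        "b": b,
        "epu": epu,
        "cquad": cquad,
        "ev": ev,
        "kk": kk,
        "boundary_events": int(boundary.sum()),
    }


def score_and_information(
    data: GroupedDataset,
    x,
    params: ModelParams,
    free_intervals=None,
    with_per_sample: bool = True,
) -> ScoreBundle:
    """Analytic score and averaged observed information at ``params``.

    The baseline block is differentiated on the zeta scale.  ``free_intervals``
    selects which interval parameters are treated as free; by default every
    interval with ``alpha_j`` strictly inside (0, 1) and at least one sample
    at risk is free.  Rows/columns for non-free intervals are zero.
    """
    n, q, r = data.n, data.q, data.r
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != n:
            raise ValueError("x length mismatch")
        if not np.all(np.isfinite(x)):
            raise ValueError("x must be finite")
    P = derivative_pieces(data, x, params)
    L, w, a, b, epu, cquad, ev, kk = (
        P["L"], P["w"], P["a"], P["b"], P["epu"], P["cquad"], P["ev"], P["kk"],
    )
    at_risk_past = _suffix_sums(kk, np.ones(n), r) > 0
    d_j = np.bincount(kk[ev], minlength=r)
    if free_intervals is None:
        free = (
            (params.alpha[:r] > 0)
            & (params.alpha[:r] < 1)
            & ~np.isnan(params.alpha[:r])
            & (at_risk_past | (d_j > 0))
        )
    else:
        free = np.zeros(r, dtype=bool)
        free[np.asarray(free_intervals)] = True
    Lf = np.where(free, L, 0.0)

    xv = x if x is not None else np.zeros(n)
    Z = data.covariates

    # score -----------------------------------------------------------------
    s_beta = float(xv @ a)
    s_theta = Z.T @ a if q else np.zeros(0)
    s_zeta = Lf * _suffix_sums(kk, w, r) + _event_sums(kk[ev], epu[ev], r)
    s_zeta[~free] = 0.0

    # Hessian (sum form), then averaged negative blocks ---------------------
    def cross(v: np.ndarray) -> np.ndarray:
        out = Lf * _suffix_sums(kk, v * w, r) + _event_sums(kk[ev], (v * cquad)[ev], r)
        out[~free] = 0.0
        return out

    H_bb = float(xv @ (b * xv))
    H_bt = Z.T @ (b * xv) if q else np.zeros(0)
    H_tt = Z.T @ (b[:, None] * Z) if q else np.zeros((0, 0))
    H_bz = cross(xv)
    H_tz = np.vstack([cross(Z[:, c]) for c in range(q)]) if q else np.zeros((0, r))
    H_zz = Lf * _suffix_sums(kk, w, r) + _event_sums(kk[ev], cquad[ev], r)
    H_zz[~free] = 0.0

    info_bb = -H_bb / n
    info_bn = -np.concatenate([H_bt, H_bz]) / n
    nn = np.zeros((q + r, q + r))
    nn[:q, :q] = H_tt
    nn[:q, q:] = H_tz
    nn[q:, :q] = H_tz.T
    nn[q:, q:] = np.diag(H_zz)
    info_nn = -nn / n

    # per-sample rows -------------------------------------------------------
    if with_per_sample:
        M = np.arange(r)[None, :] < kk[:, None]
        Pz = np.where(M, w[:, None] * Lf[None, :], 0.0)
        Pz[ev, kk[ev]] = epu[ev]
        Pz[:, ~free] = 0.0
        per_sample = np.hstack(
            [(xv * a)[:, None], Z * a[:, None] if q else np.zeros((n, 0)), Pz]
        )
    else:
        per_sample = None

    score = np.concatenate([[s_beta], s_theta, s_zeta])
    eta_free = np.concatenate([np.ones(q, dtype=bool), free])
    flags = {}
    if P["boundary_events"]:
        flags["boundary_events"] = P["boundary_events"]
    return ScoreBundle(
        score=score,
        per_sample_scores=per_sample,
        info_bb=info_bb,
        info_bn=info_bn,
        info_nn=info_nn,
        n=n,
        eta_free=eta_free,
        flags=flags,
    )
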