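"""Null-model (no variant effect) nuisance-parameter estimation.

The nuisance parameters of the grouped proportional-hazards model are
``eta = (alpha, theta)``: per-interval baseline survival probabilities and
covariate effects.  They are estimated once by maximum likelihood under
``H0: beta = 0`` and reused across every variant tested, which is what makes
a genome-wide scan with this model cheap.

With no covariates the MLE has the classical actuarial (life-table) closed
form ``alpha_j = 1 - d_j / (d_j + s_j)`` where ``d_j`` counts events in
interval ``j`` and ``s_j`` counts samples at risk beyond it.  That closed
form initialises the Newton iteration in the general case and serves as an
exact oracle for it when ``q = 0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grouped_model import (
    GroupedDataset,
    ModelParams,
    log_likelihood,
    score_and_information,
    alpha_to_zeta,
)

logger = logging.getLogger(__name__)

__all__ = ["NuisanceEstimate", "interval_counts", "life_table_alpha", "fit_null"]


@dataclass
class NuisanceEstimate:
    """MLE of ``(alpha, theta)`` under the null of no variant effect."""

    alpha_hat: np.ndarray  # (r,) with NaN where undefined
    theta_hat: np.ndarray  # (q,)
    free_intervals: np.ndarray  # indices of intervals estimated freely
    fixed_one: np.ndarray  # intervals fixed at alpha = 1 (no events)
    fixed_zero: np.ndarray  # intervals fixed at alpha = 0 (no survivors)
    dropped: np.ndarray  # intervals with no information at all
    converged: bool
    n_iter: int
    grad_norm: float
    loglik: float
    fitted_on: np.ndarray  # sample ids used in the fit
    n_excluded: int = 0  # samples dropped for missing covariates
    flags: dict = field(default_factory=dict)


def interval_counts(data: GroupedDataset):
    """Event counts ``d_j``, survivor counts ``s_j`` and at-risk ``R_j`` per interval.

    A sample ``(k, delta=1)`` is at risk through interval ``k``; a censored
    sample ``(k, delta=0)`` only through ``k - 1``.  Hence
    ``s_j = #{k > j}`` and ``R_j = d_j + s_j``.
    """
    r = data.r
    kk = data.k - 1
    d = np.bincount(kk[data.delta == 1], minlength=r).astype(float)
    n_by_k = np.bincount(kk, minlength=r).astype(float)
    s = data.n - np.cumsum(n_by_k)  # s[j] = #{samples with k - 1 > j}
    return d, s, d + s


def life_table_alpha(data: GroupedDataset):
    """Closed-form actuarial estimator ``alpha_j = 1 - d_j / (d_j + s_j)``.

    Covariates are ignored.  Intervals with no at-risk samples get NaN and
    are reported in the flags.
    """
    d, s, R = interval_counts(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = 1.0 - d / R
    alpha[R == 0] = np.nan
    flags = {}
    undefined = np.flatnonzero(R == 0)
    if undefined.size:
        flags["undefined_intervals"] = undefined
    if not np.any(R > 0) or np.all(np.isnan(alpha)):
        flags["no_information"] = True
    return alpha, flags


def _check_full_rank(Z: np.ndarray) -> None:
    q = Z.shape[1]
    if q == 0:
        return
    if np.linalg.matrix_rank(Z) == q:
        return
    bad = []
    prev_rank = 0
    for j in range(q):
        rank = np.linalg.matrix_rank(Z[:, : j + 1])
        if rank == prev_rank:
            bad.append(j)
        prev_rank = rank
    raise ValueError(
        f"covariate matrix is rank deficient; offending column indices: {bad}"
    )


def _classify_intervals(data: GroupedDataset):
    d, s, R = interval_counts(data)
    dropped = np.flatnonzero(R == 0)
    fixed_one = np.flatnonzero((d == 0) & (R > 0))
    fixed_zero = np.flatnonzero((d > 0) & (s == 0))
    free = np.flatnonzero((d > 0) & (s > 0))
    return free, fixed_one, fixed_zero, dropped


def _assemble_alpha(r, free, fixed_one, fixed_zero, dropped, zeta_free):
    alpha = np.full(r, np.nan)
    alpha[fixed_one] = 1.0
    alpha[fixed_zero] = 0.0
    alpha[free] = np.exp(-np.exp(zeta_free))
    return alpha


def newton_maximize(
    data: GroupedDataset,
    x,
    with_beta: bool,
    theta0: np.ndarray,
    zeta0: np.ndarray,
    free: np.ndarray,
    fixed_one: np.ndarray,
    fixed_zero: np.ndarray,
    dropped: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 20,
):
    """Newton ascent with step-halving on the packed parameter vector.

    The packed vector is ``([beta,] theta, zeta[free])``.  Returns the final
    packed point, convergence metadata and the (sum-form) negative Hessian at
    the optimum.
    """
    q = data.q
    F = free.size

    def unpack(p):
        off = 1 if with_beta else 0
        beta = p[0] if with_beta else 0.0
        theta = p[off : off + q]
        zeta = p[off + q :]
        return beta, theta, zeta

    def params_at(p):
        beta, theta, zeta = unpack(p)
        alpha = _assemble_alpha(data.r, free, fixed_one, fixed_zero, dropped, zeta)
        return ModelParams(beta, theta, alpha)

    def ll_at(p):
        if not np.all(np.isfinite(p)):
            return -np.inf
        # huge zeta overflows exp(exp(.)); such a step is simply rejected
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                return log_likelihood(data, x if with_beta else None, params_at(p))
            except (ValueError, FloatingPointError):
                return -np.inf

    def grad_negH(p):
        params = params_at(p)
        b = score_and_information(
            data, x, params, free_intervals=free, with_per_sample=False
        )
        g_eta = np.concatenate([b.score[1 : 1 + q], b.score[1 + q :][free]])
        sel = np.concatenate([np.arange(q), q + free])
        J_nn = data.n * b.info_nn[np.ix_(sel, sel)]
        if with_beta:
            g = np.concatenate([[b.score[0]], g_eta])
            J = np.zeros((1 + q + F, 1 + q + F))
            J[0, 0] = data.n * b.info_bb
            J[0, 1:] = data.n * b.info_bn[sel]
            J[1:, 0] = J[0, 1:]
            J[1:, 1:] = J_nn
        else:
            g, J = g_eta, J_nn
        return g, J

    p = np.concatenate([[0.0] if with_beta else [], theta0, zeta0]).astype(float)
    ll = ll_at(p)
    converged = False
    grad_norm = np.inf
    it = 0
    negH = None
    for it in range(1, max_iter + 1):
        g, negH = grad_negH(p)
        grad_norm = float(np.max(np.abs(g))) if g.size else 0.0
        if grad_norm <= tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(negH, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(negH, g, rcond=None)[0]
        t = 1.0
        improved = False
        for _ in range(max_halvings + 1):
            cand = p + t * step
            ll_new = ll_at(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                p, ll = cand, ll_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    else:
        it = max_iter
    if not converged and negH is not None:
        g, negH = grad_negH(p)
        grad_norm = float(np.max(np.abs(g))) if g.size else 0.0
        converged = grad_norm <= tol
    return p, ll, converged, it, grad_norm, negH


def fit_null(
    data: GroupedDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 20,
) -> NuisanceEstimate:
    """Maximum-likelihood estimate of ``eta = (alpha, theta)`` at ``beta = 0``.

    Samples with missing covariates are excluded (with a logged count).
    Intervals with no events but at-risk samples are fixed at ``alpha = 1``;
    intervals with events but no survivors are fixed at ``alpha = 0``; both
    are excluded from the optimisation to avoid boundary divergence.
    Deterministic given the data; invariant to sample order.
    """
    flags = {}
    n_excluded = 0
    if data.q:
        complete = ~np.any(np.isnan(data.covariates), axis=1)
        n_excluded = int((~complete).sum())
        if n_excluded:
            logger.info("excluding %d samples with missing covariates", n_excluded)
            data = data.subset(complete)
    if not np.any(data.delta == 1):
        raise ValueError("null model undefined: no events in the data")
    if data.q:
        _check_full_rank(data.covariates)

    free, fixed_one, fixed_zero, dropped = _classify_intervals(data)
    if fixed_one.size:
        warnings.warn(
            f"intervals {list(fixed_one)} have no events; alpha fixed at 1",
            stacklevel=2,
        )
        flags["fixed_one"] = fixed_one
    if fixed_zero.size:
        flags["boundary_zero"] = fixed_zero
    lt_alpha, _ = life_table_alpha(data)
    zeta0 = alpha_to_zeta(lt_alpha[free])
    theta0 = np.zeros(data.q)

    p, ll, converged, n_iter, grad_norm, _ = newton_maximize(
        data,
        None,
        False,
        theta0,
        zeta0,
        free,
        fixed_one,
        fixed_zero,
        dropped,
        tol=tol,
        max_iter=max_iter,
        max_halvings=max_halvings,
    )
    theta_hat = p[: data.q]
    zeta_hat = p[data.q :]
    alpha_hat = _assemble_alpha(data.r, free, fixed_one, fixed_zero, dropped, zeta_hat)
    return NuisanceEstimate(
        alpha_hat=alpha_hat,
        theta_hat=theta_hat,
        free_intervals=free,
        fixed_one=fixed_one,
        fixed_zero=fixed_zero,
        dropped=dropped,
        converged=bool(converged),
        n_iter=n_iter,
        grad_norm=grad_norm,
        loglik=ll,
        fitted_on=np.asarray(data.sample_ids),
        n_excluded=n_excluded,
        flags=flags,
    )
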