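"""Per-variant efficient score tests and genome-wide scan orchestration.

For each variant ``x`` the hypothesis ``H0: beta = 0`` is tested with the
efficient score statistic

    W = (sum_i S_beta(0, eta_hat))^2
        / [ n * ( Ibar_bb - Ibar_bn Ibar_nn^{-1} Ibar_bn^T ) ],

where ``eta_hat`` is the null MLE of the nuisance parameters (fitted once
and reused for every variant) and the ``Ibar`` blocks are the averaged
observed information evaluated at ``(0, eta_hat)``.  Under the null, ``W``
is asymptotically chi-square with 1 degree of freedom.

Missing genotypes are handled by complete-case analysis per variant: the
score and information sums are restricted to samples with a non-missing
dosage, while ``eta_hat`` stays the global null fit (consistent for every
subset since the null model does not involve the variant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .grouped_model import GroupedDataset, ModelParams, derivative_pieces
from .null_fit import (
    NuisanceEstimate,
    fit_null,
    newton_maximize,
    _classify_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullScoreEngine",
    "efficient_score_test",
    "estimate_beta",
    "scan",
    "bonferroni_adjust",
    "storey_qvalues",
    "folded_maf",
]

RESULT_COLUMNS = [
    "variant_id",
    "n",
    "maf",
    "stat",
    "pvalue",
    "fwer_p",
    "qvalue",
    "beta_hat",
    "status",
]


def folded_maf(x: np.ndarray) -> float:
    """Minor allele frequency from dosages in [0, 2]: mean/2 folded to <= 0.5."""
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan
    f = float(np.mean(x) / 2.0)
    return min(f, 1.0 - f)


class NullScoreEngine:
    """Caches null-model quantities so each variant test is O(n).

    All per-sample derivative ingredients at ``(beta=0, eta_hat)`` are
    independent of the variant; only the reductions against ``x`` (and the
    complete-case mask) are variant specific.
    """

    def __init__(self, data: GroupedDataset, eta: NuisanceEstimate):
        if not eta.converged:
            raise ValueError("null fit did not converge; refusing to test")
        keep = np.isin(data.sample_ids, eta.fitted_on)
        if not keep.all():
            data = data.subset(keep)
        self.data = data
        self.eta = eta
        params = ModelParams(0.0, eta.theta_hat, np.nan_to_num(eta.alpha_hat, nan=1.0))
        # NaN alpha (dropped intervals) set to 1: inert in every term
        P = derivative_pieces(data, None, params)
        self.w, self.a, self.b = P["w"], P["a"], P["b"]
        self.cquad, self.epu, self.ev, self.kk = P["cquad"], P["epu"], P["ev"], P["kk"]
        self.free = eta.free_intervals
        self.Lf = np.zeros(data.r)
        self.Lf[self.free] = np.log(eta.alpha_hat[self.free])
        self.Z = data.covariates
        self.q = data.q
        self.n = data.n
        self.r = data.r
        self._full_mask = np.ones(self.n, dtype=bool)
        self._J_nn_full = None
        self._per_sample_eta = None

    # -- helpers ------------------------------------------------------------
    def _suffix(self, weights, mask) -> np.ndarray:
        kk = self.kk[mask]
        w = weights[mask]
        byk = np.bincount(kk, weights=w, minlength=self.r)
        return w.sum() - np.cumsum(byk)

    def _event_sum(self, weights, mask) -> np.ndarray:
        sel = self.ev & mask
        return np.bincount(self.kk[sel], weights=weights[sel], minlength=self.r)

    def _cross(self, v, mask) -> np.ndarray:
        out = self.Lf * self._suffix(v * self.w, mask) + self._event_sum(
            v * self.cquad, mask
        )
        return out[self.free]

    def _J_nn(self, mask) -> np.ndarray:
        full = mask is self._full_mask or mask.all()
        if full and self._J_nn_full is not None:
            return self._J_nn_full
        q, free = self.q, self.free
        Zm = self.Z[mask] if not full else self.Z
        bm = self.b[mask] if not full else self.b
        H_tt = Zm.T @ (bm[:, None] * Zm) if q else np.zeros((0, 0))
        H_tz = (
            np.vstack([self._cross(self.Z[:, c], mask) for c in range(q)])
            if q
            else np.zeros((0, free.size))
        )
        H_zz = (
            self.Lf * self._suffix(self.w, mask) + self._event_sum(self.cquad, mask)
        )[free]
        J = np.zeros((q + free.size, q + free.size))
        J[:q, :q] = -H_tt
        J[:q, q:] = -H_tz
        J[q:, :q] = -H_tz.T
        J[q:, q:] = np.diag(-H_zz)
        if full:
            self._J_nn_full = J
        return J

    def per_sample_eta_scores(self) -> np.ndarray:
        """(n, q + F) per-sample scores for the free nuisance directions."""
        if self._per_sample_eta is None:
            M = self.free[None, :] < self.kk[:, None]
            Pz = np.where(M, self.w[:, None] * self.Lf[self.free][None, :], 0.0)
            in_free = np.isin(self.kk, self.free)
            pos = np.searchsorted(self.free, self.kk[self.ev & in_free])
            rows = np.flatnonzero(self.ev & in_free)
            Pz[rows, pos] = self.epu[rows]
            theta_part = self.Z * self.a[:, None] if self.q else np.zeros((self.n, 0))
            self._per_sample_eta = np.hstack([theta_part, Pz])
        return self._per_sample_eta

    # -- the test -----------------------------------------------------------
    def test(self, x: np.ndarray, return_contributions: bool = False) -> dict:
        """Efficient score test of ``H0: beta = 0`` for dosage vector ``x``.

        NaN entries of ``x`` are treated as missing (complete-case).
        """
        x = np.asarray(x, dtype=float)
        if x.shape[0] != self.n:
            raise ValueError("x length does not match the fitted sample set")
        mask = ~np.isnan(x)
        n_cc = int(mask.sum())
        maf = folded_maf(x)
        out = {
            "n": n_cc,
            "maf": maf,
            "stat": np.nan,
            "pvalue": np.nan,
            "status": "ok",
        }
        if n_cc == 0:
            out["status"] = "failed"
            return out
        xm = np.where(mask, x, 0.0)
        if np.ptp(x[mask]) == 0.0:
            out["status"] = "monomorphic"
            return out

        S_b = float(xm @ self.a)
        J_bb = -float(xm @ (self.b * xm))
        J_bt = -(self.Z.T @ (self.b * xm)) if self.q else np.zeros(0)
        J_bz = -self._cross(xm, mask if n_cc < self.n else self._full_mask)
        J_bn = np.concatenate([J_bt, J_bz])
        J_nn = self._J_nn(mask if n_cc < self.n else self._full_mask)

        status = "ok"
        try:
            sol = np.linalg.solve(J_nn, J_bn)
        except np.linalg.LinAlgError:
            warnings.warn("singular nuisance information; using pseudo-inverse")
            sol = np.linalg.pinv(J_nn) @ J_bn
            status = "boundary"
        J_eff = J_bb - float(J_bn @ sol)
        if not np.isfinite(J_eff) or J_eff <= max(1e-12 * abs(J_bb), 1e-300):
            out["status"] = "monomorphic"
            return out
        W = S_b * S_b / J_eff
        out.update(
            stat=W, pvalue=float(stats.chi2.sf(W, df=1)), status=status, j_eff=J_eff
        )
        if return_contributions:
            contrib = xm * self.a - self.per_sample_eta_scores() @ sol
            contrib[~mask] = 0.0
            out["contributions"] = contrib
        return out


def efficient_score_test(data: GroupedDataset, x, eta_hat: NuisanceEstimate):
    """One-shot efficient score test; see :class:`NullScoreEngine`.

    Returns ``(W, pvalue, contributions)`` where contributions are the
    per-sample efficient (nuisance-projected) scores, summing to the score
    numerator when no genotypes are missing.
    """
    engine = NullScoreEngine(data, eta_hat)
    res = engine.test(np.asarray(x, dtype=float), return_contributions=True)
    if res["status"] == "monomorphic":
        raise ValueError("x is constant on complete cases: zero efficient information")
    return res["stat"], res["pvalue"], res["contributions"]


def estimate_beta(
    data: GroupedDataset,
    x,
    init: NuisanceEstimate,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Joint MLE of ``(beta, theta, alpha)`` for one variant.

    Newton maximisation of the full grouped likelihood initialised at
    ``(0, eta_hat)``; the standard error comes from the inverse observed
    information at the optimum.  Returns ``(beta_hat, se, status)`` with
    status ``failed`` on separation (|beta| > 50) or non-convergence.
    """
    x = np.asarray(x, dtype=float)
    mask = ~np.isnan(x)
    if data.q:
        mask &= ~np.any(np.isnan(data.covariates), axis=1)
    sub = data.subset(mask)
    xs = x[mask]
    if np.ptp(xs) == 0.0:
        return np.nan, np.nan, "monomorphic"
    free, fixed_one, fixed_zero, dropped = _classify_intervals(sub)
    zeta0 = np.log(-np.log(init.alpha_hat[free]))
    p, ll, converged, n_iter, grad_norm, negH = newton_maximize(
        sub,
        xs,
        True,
        init.theta_hat.copy(),
        zeta0,
        free,
        fixed_one,
        fixed_zero,
        dropped,
        tol=tol,
        max_iter=max_iter,
    )
    beta_hat = float(p[0])
    if abs(beta_hat) > 50:
        return beta_hat, np.nan, "failed"
    if not converged:
        return beta_hat, np.nan, "failed"
    try:
        se = float(np.sqrt(np.linalg.inv(negH)[0, 0]))
    except np.linalg.LinAlgError:
        se = np.nan
    return beta_hat, se, "ok"


def bonferroni_adjust(p: np.ndarray, m: int) -> np.ndarray:
    """Family-wise error rate adjustment: ``min(1, m * p)`` elementwise."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, m * p)


def storey_qvalues(p: np.ndarray, lambdas: Optional[np.ndarray] = None):
    """Storey q-values with smoother-based ``pi0`` estimation.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on the
    grid ``lambda = 0.05, 0.10, ..., 0.95``, smoothed with a cubic fit and
    read off at ``lambda = 0.95``, then clipped into (0, 1].  With fewer
    than 20 p-values the smoother is unreliable and ``pi0 = 1`` is used
    (reducing to Benjamini–Hochberg-style monotonised values).

    Returns ``(q, pi0)`` with q in the input order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 1:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m < 20:
        warnings.warn("fewer than 20 p-values: falling back to pi0 = 1")
        pi0 = 1.0
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        coeffs = np.polyfit(lambdas, pi0_lam, 3)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * ps / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def _scan_chunk(engine, G, idx, want_beta, data, eta, refit, collect_contrib):
    rows = []
    contribs = {}
    for j in idx:
        x = G[:, j]
        if np.all(np.isnan(x)):
            rows.append((j, 0, np.nan, np.nan, np.nan, np.nan, "failed"))
            continue
        if refit:
            mask = ~np.isnan(x)
            eta_j = fit_null(data.subset(mask))
            eng_j = NullScoreEngine(data.subset(mask), eta_j)
            res = eng_j.test(x[mask], return_contributions=collect_contrib)
            if collect_contrib and "contributions" in res:
                full = np.zeros(data.n)
                full[mask] = res["contributions"]
                res["contributions"] = full
        else:
            res = engine.test(x, return_contributions=collect_contrib)
        beta_hat = np.nan
        if want_beta and res["status"] in ("ok", "boundary"):
            beta_hat, _, bstat = estimate_beta(data, x, eta)
            if bstat == "failed":
                res["status"] = "failed"
        if collect_contrib and "contributions" in res:
            contribs[j] = res["contributions"]
        rows.append(
            (j, res["n"], res["maf"], res["stat"], res["pvalue"], beta_hat, res["status"])
        )
    return rows, contribs


def scan(
    data: GroupedDataset,
    genotypes: np.ndarray,
    variant_ids=None,
    eta_hat: Optional[NuisanceEstimate] = None,
    estimate_betas: bool = False,
    cores: int = 1,
    refit_null_per_variant: bool = False,
    return_contributions: bool = False,
):
    """Genome-wide scan: efficient score test for every genotype column.

    The null nuisance fit is computed once (on phenotype-complete samples)
    and reused; per-variant work is restricted to samples with non-missing
    dosage.  Output is identical for any ``cores`` value and any variant
    ordering.

    Returns a DataFrame with columns ``variant_id, n, maf, stat, pvalue,
    fwer_p, qvalue, beta_hat, status`` (and, optionally, the n-by-m matrix
    of per-sample efficient score contributions).
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] != data.n:
        raise ValueError("genotype matrix must be n x m with rows matching samples")
    m = G.shape[1]
    if variant_ids is None:
        variant_ids = np.array([f"v{j}" for j in range(m)])
    variant_ids = np.asarray(variant_ids)
    if variant_ids.shape[0] != m:
        raise ValueError("variant_ids length mismatch")
    if eta_hat is None:
        eta_hat = fit_null(data)
    keep = np.isin(data.sample_ids, eta_hat.fitted_on)
    if not keep.all():
        data = data.subset(keep)
        G = G[keep]
    engine = NullScoreEngine(data, eta_hat)
    chunks = np.array_split(np.arange(m), max(1, min(cores * 4, m)))
    chunks = [c for c in chunks if c.size]
    if cores > 1:
        results = Parallel(n_jobs=cores)(
            delayed(_scan_chunk)(
                engine, G, c, estimate_betas, data, eta_hat,
                refit_null_per_variant, return_contributions,
            )
            for c in chunks
        )
    else:
        results = [
            _scan_chunk(
                engine, G, c, estimate_betas, data, eta_hat,
                refit_null_per_variant, return_contributions,
            )
            for c in chunks
        ]
    rows = [row for chunk_rows, _ in results for row in chunk_rows]
    rows.sort(key=lambda t: t[0])
    df = pd.DataFrame(
        rows, columns=["_j", "n", "maf", "stat", "pvalue", "beta_hat", "status"]
    )
    df.insert(0, "variant_id", variant_ids[df["_j"].to_numpy()])
    df = df.drop(columns="_j")
    ok = df["status"].isin(["ok", "boundary"]) & df["pvalue"].notna()
    m_ok = int((df["status"] == "ok").sum())
    df["fwer_p"] = np.nan
    df.loc[ok, "fwer_p"] = bonferroni_adjust(df.loc[ok, "pvalue"].to_numpy(), m_ok)
    df["qvalue"] = np.nan
    strict_ok = (df["status"] == "ok") & df["pvalue"].notna()
    if strict_ok.sum() >= 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q, _ = storey_qvalues(df.loc[strict_ok, "pvalue"].to_numpy())
        df.loc[strict_ok, "qvalue"] = q
    df = df[RESULT_COLUMNS]
    if return_contributions:
        contribs = {}
        for _, c in results:
            contribs.update(c)
        C = np.full((data.n, m), np.nan)
        for j, col in contribs.items():
            C[:, j] = col
        return df, C
    return df
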