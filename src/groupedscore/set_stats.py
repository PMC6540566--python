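"""Gene- and pathway-level statistics from per-sample score contributions.

The variant scan can emit, for each variant, the per-sample efficient
(nuisance-projected) score contributions ``u_ij``.  A set of variants is
then tested jointly with a variance-component (SKAT-type) statistic

    Q = sum_j w_j S_j^2,   S_j = sum_i u_ij,

with minor-allele-frequency weights ``w_j = Beta(maf_j; 1, 25)^2`` by
default, so rare variants are up-weighted.  Under the null, ``Q`` is
distributed as a weighted mixture of chi-square(1) variables whose weights
are the eigenvalues of ``W^{1/2} Sigma W^{1/2}``; ``Sigma`` is estimated as
``n`` times the sample covariance of the per-sample contribution rows
(already projected for the nuisance parameters, so no per-set refitting is
needed).  A user-supplied aggregation function can replace the SKAT
statistic entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy import stats

from ._quadform import quadform_sf

__all__ = ["GeneSetResult", "skat_stat", "custom_stat", "gene_scan", "beta_maf_weights"]


@dataclass
class GeneSetResult:
    set_id: str
    m_variants: int
    Q: float
    pvalue: float
    method: str  # "skat" or "custom"
    weights: Optional[np.ndarray] = None
    status: str = "ok"
    message: str = ""
    flags: dict = field(default_factory=dict)


def beta_maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Squared Beta-density MAF weights (the canonical SKAT choice)."""
    return stats.beta.pdf(np.asarray(mafs, dtype=float), a, b) ** 2


def skat_stat(
    contributions: np.ndarray,
    mafs: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    set_id: str = "",
) -> GeneSetResult:
    """SKAT variance-component test on a set's contribution matrix.

    Parameters
    ----------
    contributions : (n, m) array
        Per-sample efficient score contributions for the set's variants.
    mafs : (m,) array, optional
        Minor allele frequencies used for the default Beta(1, 25) weights.
    weights : (m,) array, optional
        Explicit non-negative weights; overrides ``mafs``.
    """
    U = np.atleast_2d(np.asarray(contributions, dtype=float))
    n, m = U.shape
    if m < 1:
        raise ValueError("set must contain at least one variant")
    if weights is None:
        if mafs is None:
            raise ValueError("either mafs or explicit weights are required")
        weights = beta_maf_weights(mafs)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != m or np.any(weights < 0):
        raise ValueError("weights must be non-negative, one per variant")
    S = U.sum(axis=0)
    Q = float(np.sum(weights * S**2))
    if weights.sum() == 0:
        warnings.warn(f"set {set_id!r}: all weights are zero")
        return GeneSetResult(set_id, m, 0.0, 1.0, "skat", weights, flags={"zero_weight": True})
    Sigma = n * np.atleast_2d(np.cov(U, rowvar=False))
    sqw = np.sqrt(weights)
    K = sqw[:, None] * Sigma * sqw[None, :]
    lam = np.linalg.eigvalsh(K)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    if lam.size == 0:
        raise ValueError(f"set {set_id!r}: contribution covariance has rank 0")
    p = quadform_sf(Q, lam)
    return GeneSetResult(set_id, m, Q, float(max(min(p, 1.0), np.nextafter(0, 1))),
                         "skat", weights)


def custom_stat(
    contributions: np.ndarray,
    user_function: Callable[[np.ndarray], tuple],
    set_id: str = "",
) -> GeneSetResult:
    """Wrap a user aggregation function mapping contributions to ``(Q, p)``."""
    U = np.atleast_2d(np.asarray(contributions, dtype=float))
    m = U.shape[1]
    try:
        Q, p = user_function(U)
    except Exception as exc:  # captured, not propagated: one bad set must not kill a run
        return GeneSetResult(
            set_id, m, np.nan, np.nan, "custom", status="failed", message=str(exc)
        )
    p = float(min(max(float(p), np.nextafter(0, 1)), 1.0))
    return GeneSetResult(set_id, m, float(Q), p, "custom")


def gene_scan(
    contributions: np.ndarray,
    variant_ids: Sequence[str],
    sets: Dict[str, Sequence[str]],
    mafs: Optional[np.ndarray] = None,
    statuses: Optional[Sequence[str]] = None,
    user_function: Optional[Callable] = None,
) -> list:
    """Apply the set statistic to every gene/pathway definition.

    Only variants with ``ok`` status (when statuses are given) and present
    in the contribution matrix enter a set; sets with no usable variants are
    flagged ``failed``.
    """
    variant_ids = np.asarray(variant_ids)
    col = {v: j for j, v in enumerate(variant_ids)}
    usable = np.ones(variant_ids.shape[0], dtype=bool)
    if statuses is not None:
        usable = np.asarray(statuses) == "ok"
    results = []
    for set_id, members in sets.items():
        idx = [col[v] for v in members if v in col and usable[col[v]]]
        if not idx:
            results.append(
                GeneSetResult(set_id, 0, np.nan, np.nan,
                              "custom" if user_function else "skat",
                              status="failed", message="no usable variants")
            )
            continue
        U = contributions[:, idx]
        U = U[~np.any(np.isnan(U), axis=1)]
        if user_function is not None:
            results.append(custom_stat(U, user_function, set_id=set_id))
        else:
            results.append(
                skat_stat(U, mafs=mafs[idx] if mafs is not None else None, set_id=set_id)
            )
    return results
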