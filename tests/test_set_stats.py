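"""SKAT-type set statistics on per-sample score contributions."""

import warnings

import numpy as np
import pytest
from scipy import stats

from groupedscore.null_fit import fit_null
from groupedscore.set_stats import GeneSetResult, custom_stat, gene_scan, skat_stat
from groupedscore.simulate import SimulationConfig, simulate_grouped
from groupedscore.variant_scan import NullScoreEngine, scan
from groupedscore._quadform import liu_sf, quadform_sf


@pytest.fixture(scope="module")
def contribution_matrix():
    """Null cohort with independent variants and their contribution matrix."""
    cfg = SimulationConfig(n=300, beta=0.0, maf=0.3, target_event_rate=0.5, seed=99)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data, _, _ = simulate_grouped(cfg)
        eta = fit_null(data)
    rng = np.random.default_rng(7)
    mafs = rng.uniform(0.05, 0.5, 9)
    G = np.column_stack([rng.binomial(2, f, data.n).astype(float) for f in mafs])
    eng = NullScoreEngine(data, eta)
    U = np.column_stack(
        [eng.test(G[:, j], return_contributions=True)["contributions"] for j in range(9)]
    )
    return U, mafs, data.n


def test_single_variant_reduces_to_marginal_test(contribution_matrix):
    U, mafs, n = contribution_matrix
    u = U[:, 0]
    res = skat_stat(u[:, None], weights=np.array([1.0]))
    S = u.sum()
    sigma = n * float(np.cov(u))
    p_marginal = stats.chi2.sf(S * S / sigma, df=1)
    assert res.Q == pytest.approx(S * S, rel=1e-12)
    assert res.pvalue == pytest.approx(p_marginal, abs=1e-8)


def test_zero_weights_give_trivial_result(contribution_matrix):
    U, _, _ = contribution_matrix
    with pytest.warns(UserWarning, match="zero"):
        res = skat_stat(U[:, :3], weights=np.zeros(3))
    assert res.Q == 0.0 and res.pvalue == 1.0


def test_pvalue_matches_mixture_monte_carlo(contribution_matrix):
    """Imhof/Davies p agrees with simulation from the fitted chi-square mixture."""
    U, mafs, n = contribution_matrix
    sub = U[:, :3]
    w = np.ones(3)
    res = skat_stat(sub, weights=w)
    Sigma = n * np.cov(sub, rowvar=False)
    lam = np.linalg.eigvalsh(Sigma)
    lam = lam[lam > 0]
    rng = np.random.default_rng(1)
    draws = (lam[None, :] * rng.chisquare(1, (100_000, lam.size))).sum(axis=1)
    p_mc = (draws > res.Q).mean()
    se = np.sqrt(max(p_mc * (1 - p_mc), 1e-9) / 100_000)
    assert abs(res.pvalue - p_mc) < 3 * se + 1e-4


def test_custom_function_self_consistency(contribution_matrix):
    U, mafs, n = contribution_matrix

    def builtin(Umat):
        r = skat_stat(Umat, mafs=mafs[:4])
        return r.Q, r.pvalue

    res = custom_stat(U[:, :4], builtin)
    ref = skat_stat(U[:, :4], mafs=mafs[:4])
    assert res.Q == ref.Q and res.pvalue == ref.pvalue


def test_custom_constant_passthrough(contribution_matrix):
    U, _, _ = contribution_matrix
    res = custom_stat(U, lambda Umat: (0.0, 1.0))
    assert res.Q == 0.0 and res.pvalue == 1.0 and res.method == "custom"


def test_custom_function_failure_captured(contribution_matrix):
    U, _, _ = contribution_matrix

    def broken(_):
        raise RuntimeError("boom")

    res = custom_stat(U, broken)
    assert res.status == "failed" and "boom" in res.message


def test_sign_flip_permutation_agrees_with_davies(contribution_matrix):
    """Unweighted sum-of-squared-scores with a row sign-flip null vs Davies p.

    Sign flips preserve the second-moment structure of the contributions, so
    the permutation p-value should agree with the analytic mixture p-value
    up to permutation noise.
    """
    U, _, n = contribution_matrix
    sub = U[:, 3:6]
    rng = np.random.default_rng(0)

    Q_obs = float((sub.sum(axis=0) ** 2).sum())
    B = 500
    flips = rng.choice([-1.0, 1.0], size=(B, n))
    Q_perm = np.array([(((f[:, None] * sub).sum(axis=0)) ** 2).sum() for f in flips])
    p_perm = (1 + (Q_perm >= Q_obs).sum()) / (B + 1)

    p_davies = skat_stat(sub, weights=np.ones(3)).pvalue
    ci = 2.58 * np.sqrt(p_davies * (1 - p_davies) / B)
    assert abs(p_perm - p_davies) < ci + 0.02


def test_q_invariant_to_row_order_and_splitting(contribution_matrix):
    U, mafs, _ = contribution_matrix
    rng = np.random.default_rng(3)
    perm = rng.permutation(U.shape[0])
    a = skat_stat(U, mafs=mafs)
    b = skat_stat(U[perm], mafs=mafs)
    assert a.Q == pytest.approx(b.Q, rel=1e-12)
    assert a.pvalue == pytest.approx(b.pvalue, rel=1e-9)


def test_null_set_pvalues_uniform():
    """Under the global null, set p-values are uniform across replicate cohorts.

    Each replicate draws a fresh cohort (the chi-square-mixture null is an
    unconditional statement; conditioning on one cohort leaves finite-sample
    cohort effects in the p-values).
    """
    from dataclasses import replace

    from groupedscore.simulate import calibrate_censoring

    cfg = SimulationConfig(n=600, beta=0.0, maf=0.3, target_event_rate=0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = replace(cfg, c_max=calibrate_censoring(cfg), target_event_rate=None)
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(400):
            data, _, _ = simulate_grouped(cfg, rng=rng)
            eta = fit_null(data)
            eng = NullScoreEngine(data, eta)
            G = rng.binomial(2, 0.3, (data.n, 3)).astype(float)
            U = np.column_stack(
                [
                    eng.test(G[:, j], return_contributions=True)["contributions"]
                    for j in range(3)
                ]
            )
            pvals.append(skat_stat(U, weights=np.ones(3)).pvalue)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_gene_scan_filters_statuses(contribution_matrix):
    U, mafs, _ = contribution_matrix
    vids = np.array([f"v{j}" for j in range(9)])
    statuses = np.array(["ok"] * 8 + ["monomorphic"])
    sets = {"gA": ["v0", "v1"], "gB": ["v8"], "gC": ["nope"]}
    res = gene_scan(U, vids, sets, mafs=mafs, statuses=statuses)
    by_id = {g.set_id: g for g in res}
    assert by_id["gA"].m_variants == 2 and by_id["gA"].status == "ok"
    assert by_id["gB"].status == "failed"  # only member filtered out
    assert by_id["gC"].status == "failed"


def test_liu_fallback_reasonable():
    lam = np.array([1.5, 0.7])
    # chi2_2-like check: equal weights 1 reduce to chi2(2)
    assert quadform_sf(3.0, np.array([1.0, 1.0])) == pytest.approx(np.exp(-1.5), rel=1e-6)
    assert 0 < liu_sf(5.0, lam) < 1
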