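"""Efficient score tests, per-variant MLE, scan, and multiple testing."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import optimize, stats

from groupedscore.grouped_model import (
    GroupedDataset,
    ModelParams,
    log_likelihood,
    score_and_information,
    zeta_to_alpha,
    alpha_to_zeta,
)
from groupedscore.null_fit import fit_null, _classify_intervals
from groupedscore.variant_scan import (
    NullScoreEngine,
    bonferroni_adjust,
    estimate_beta,
    folded_maf,
    scan,
    storey_qvalues,
)
from groupedscore.simulate import SimulationConfig, calibrate_censoring, simulate_grouped


def test_monomorphic_variant_has_no_statistic(null_cohort):
    data, _, eta = null_cohort
    res = NullScoreEngine(data, eta).test(np.ones(data.n))
    assert res["status"] == "monomorphic"
    assert np.isnan(res["stat"])


def test_statistic_affine_invariant_in_x(null_cohort):
    data, x, eta = null_cohort
    eng = NullScoreEngine(data, eta)
    W = eng.test(x)["stat"]
    for a, b in [(2.0, 0.0), (-1.3, 0.7), (0.25, -4.0)]:
        assert eng.test(a * x + b)["stat"] == pytest.approx(W, abs=1e-8)


def test_efficient_information_block_inverse_identity():
    cfg = SimulationConfig(n=25, beta=0.0, maf=0.3, target_event_rate=0.6, seed=3,
                           r=3, tau=2.0)
    data, x, _ = simulate_grouped(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eta = fit_null(data)
    params = ModelParams(0.0, eta.theta_hat, np.nan_to_num(eta.alpha_hat, nan=1.0))
    b = score_and_information(data, x, params, free_intervals=eta.free_intervals)
    sel = np.concatenate([np.arange(data.q), data.q + eta.free_intervals])
    eff = b.info_bb - b.info_bn[sel] @ np.linalg.solve(
        b.info_nn[np.ix_(sel, sel)], b.info_bn[sel]
    )
    full = np.zeros((1 + sel.size, 1 + sel.size))
    full[0, 0] = b.info_bb
    full[0, 1:] = b.info_bn[sel]
    full[1:, 0] = b.info_bn[sel]
    full[1:, 1:] = b.info_nn[np.ix_(sel, sel)]
    assert eff == pytest.approx(1.0 / np.linalg.inv(full)[0, 0], rel=1e-10)


def test_contributions_sum_to_score_numerator(null_cohort):
    data, x, eta = null_cohort
    eng = NullScoreEngine(data, eta)
    res = eng.test(x, return_contributions=True)
    S_beta = float(x @ eng.a)
    assert res["contributions"].sum() == pytest.approx(S_beta, rel=1e-10)


def test_null_statistic_is_chi_square(null_cohort):
    """Empirical W under beta=0 matches chi-square(1) (moderate-B check)."""
    cfg = SimulationConfig(n=300, beta=0.0, maf=0.3, target_event_rate=0.5)
    cfg = replace(cfg, c_max=calibrate_censoring(cfg), target_event_rate=None)
    rng = np.random.default_rng(8)
    Ws = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(800):
            data, x, _ = simulate_grouped(cfg, rng=rng)
            eta = fit_null(data)
            Ws.append(NullScoreEngine(data, eta).test(x)["stat"])
    assert stats.kstest(Ws, stats.chi2(1).cdf).pvalue > 0.01


def test_estimate_beta_matches_generic_optimizer():
    cfg = SimulationConfig(n=200, beta=0.7, maf=0.4, target_event_rate=0.6, seed=21)
    data, x, _ = simulate_grouped(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eta = fit_null(data)
        beta_hat, se, status = estimate_beta(data, x, eta)
    assert status == "ok"
    free, *_ = _classify_intervals(data)

    def negll(v):
        alpha = np.ones(data.r)
        alpha[free] = zeta_to_alpha(v[3:])
        return -log_likelihood(data, x, ModelParams(v[0], v[1:3], alpha))

    v0 = np.concatenate([[0.0], eta.theta_hat, alpha_to_zeta(eta.alpha_hat[free])])
    res = optimize.minimize(negll, v0, method="Nelder-Mead",
                            options=dict(maxiter=60000, maxfev=60000,
                                         xatol=1e-10, fatol=1e-13))
    assert beta_hat == pytest.approx(res.x[0], abs=1e-5)
    assert se > 0


def test_estimate_beta_stationarity(null_cohort):
    data, x, eta = null_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta_hat, _, status = estimate_beta(data, x, eta)
    assert status == "ok"
    # refit nuisance at beta_hat fixed is implicit: the joint gradient is 0,
    # so in particular the beta-component of the score vanishes
    free, *_ = _classify_intervals(data)
    # reconstruct the joint optimum by rerunning and checking the score there
    from groupedscore.null_fit import newton_maximize, _assemble_alpha

    p, ll, conv, *_rest = newton_maximize(
        data, x, True, eta.theta_hat.copy(), alpha_to_zeta(eta.alpha_hat[free]),
        free, np.array([], dtype=int), np.array([], dtype=int), np.array([], dtype=int),
    )
    alpha = _assemble_alpha(data.r, free, [], [], [], p[1 + data.q :])
    b = score_and_information(
        data, x, ModelParams(p[0], p[1 : 1 + data.q], alpha), free_intervals=free
    )
    assert abs(b.score[0]) < 1e-6


def test_lrt_and_score_statistic_agree_asymptotically():
    cfg = SimulationConfig(n=5000, beta=0.06, maf=0.5, target_event_rate=0.6, seed=4)
    data, x, _ = simulate_grouped(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eta = fit_null(data)
        W = NullScoreEngine(data, eta).test(x)["stat"]
        beta_hat, se, _ = estimate_beta(data, x, eta)
    free, *_ = _classify_intervals(data)
    alpha_full = np.nan_to_num(eta.alpha_hat, nan=1.0)
    from groupedscore.null_fit import newton_maximize, _assemble_alpha

    p, ll_full, *_rest = newton_maximize(
        data, x, True, eta.theta_hat.copy(), alpha_to_zeta(eta.alpha_hat[free]),
        free, np.array([], dtype=int), np.array([], dtype=int), np.array([], dtype=int),
    )
    lrt = 2 * (ll_full - eta.loglik)
    assert lrt == pytest.approx(W, rel=0.15)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def test_scan_single_variant_equals_direct_test(null_cohort):
    data, x, eta = null_cohort
    direct = NullScoreEngine(data, eta).test(x)
    df = scan(data, x[:, None], variant_ids=["v"], eta_hat=eta)
    assert df.loc[0, "pvalue"] == direct["pvalue"]
    assert df.loc[0, "stat"] == direct["stat"]
    assert df.loc[0, "fwer_p"] == direct["pvalue"]  # m = 1


def test_missing_genotype_equals_sample_deletion(null_cohort):
    data, x, eta = null_cohort
    x_miss = x.copy().astype(float)
    x_miss[7] = np.nan
    res_miss = NullScoreEngine(data, eta).test(x_miss)
    keep = np.arange(data.n) != 7
    res_del = NullScoreEngine(data.subset(keep), eta).test(x[keep])
    assert res_miss["stat"] == pytest.approx(res_del["stat"], rel=1e-10)
    assert res_miss["n"] == res_del["n"] == data.n - 1


def test_scan_invariant_to_workers_and_order(null_cohort):
    data, _, eta = null_cohort
    rng = np.random.default_rng(5)
    G = rng.binomial(2, 0.3, (data.n, 12)).astype(float)
    G[rng.random(G.shape) < 0.05] = np.nan
    ids = [f"v{j}" for j in range(12)]
    df1 = scan(data, G, variant_ids=ids, eta_hat=eta, cores=1)
    df2 = scan(data, G, variant_ids=ids, eta_hat=eta, cores=2)
    assert df1.equals(df2)
    perm = rng.permutation(12)
    df3 = scan(data, G[:, perm], variant_ids=np.array(ids)[perm], eta_hat=eta)
    df3 = df3.set_index("variant_id").loc[ids].reset_index()
    np.testing.assert_allclose(
        df1["pvalue"].to_numpy(), df3["pvalue"].to_numpy(), rtol=1e-12
    )
    np.testing.assert_allclose(
        df1["qvalue"].to_numpy(), df3["qvalue"].to_numpy(), rtol=1e-12
    )


def test_refit_null_per_variant(null_cohort):
    """Exact per-subset refitting agrees with the global-null default when
    nothing is missing, and changes only slightly under light missingness."""
    data, x, eta = null_cohort
    df_global = scan(data, x[:, None], eta_hat=eta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df_refit = scan(data, x[:, None], eta_hat=eta, refit_null_per_variant=True)
    assert df_refit.loc[0, "stat"] == pytest.approx(df_global.loc[0, "stat"], rel=1e-8)
    x_miss = x.copy()
    x_miss[:10] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df_m = scan(data, x_miss[:, None], eta_hat=eta, refit_null_per_variant=True)
    assert df_m.loc[0, "n"] == data.n - 10
    assert df_m.loc[0, "status"] == "ok"


def test_scan_status_codes_and_columns(null_cohort):
    data, x, eta = null_cohort
    G = np.column_stack([x, np.ones(data.n), np.full(data.n, np.nan)])
    df = scan(data, G, variant_ids=["a", "b", "c"], eta_hat=eta, estimate_betas=True)
    assert list(df.columns) == [
        "variant_id", "n", "maf", "stat", "pvalue", "fwer_p", "qvalue",
        "beta_hat", "status",
    ]
    assert df.loc[0, "status"] == "ok" and np.isfinite(df.loc[0, "beta_hat"])
    assert df.loc[1, "status"] == "monomorphic"
    assert df.loc[2, "status"] == "failed"


def test_folded_maf():
    assert folded_maf(np.array([2.0, 2.0, 1.0, np.nan])) == pytest.approx(1 - 5 / 6)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, m, expected",
    [(0.001, 100, 0.1), (0.02, 100, 1.0), (0.05, 1, 0.05)],
)
def test_bonferroni(p, m, expected):
    assert bonferroni_adjust(np.array([p]), m)[0] == pytest.approx(expected)


def _storey_reference(p):
    """Step-by-step independent implementation of Storey's q-values."""
    p = np.asarray(p, float)
    m = len(p)
    lambdas = [0.05 * i for i in range(1, 20)]
    pi0_vals = [sum(pi > lam for pi in p) / (m * (1 - lam)) for lam in lambdas]
    pi0 = float(np.polyval(np.polyfit(lambdas, pi0_vals, 3), 0.95))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q[i] = min(pi0 * m * p[i] / rank, prev)
        prev = q[i]
    return np.array(q), pi0


def test_storey_matches_reference(rng):
    p = rng.uniform(size=100)
    q, pi0 = storey_qvalues(p)
    q_ref, pi0_ref = _storey_reference(p)
    assert pi0 == pytest.approx(pi0_ref, abs=1e-10)
    np.testing.assert_allclose(q, q_ref, atol=1e-10)


def test_storey_all_ones():
    q, pi0 = storey_qvalues(np.ones(50))
    assert pi0 == 1.0
    np.testing.assert_allclose(q, 1.0)


def test_storey_small_m_is_bh(rng):
    p = np.sort(rng.uniform(size=10))
    with pytest.warns(UserWarning):
        q, pi0 = storey_qvalues(p)
    assert pi0 == 1.0
    bh = np.minimum.accumulate((p * 10 / np.arange(1, 11))[::-1])[::-1]
    np.testing.assert_allclose(q, bh, atol=1e-12)


def test_storey_rejects_out_of_range():
    with pytest.raises(ValueError):
        storey_qvalues(np.array([0.0, 0.5]))
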