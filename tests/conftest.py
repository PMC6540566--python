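import numpy as np
import pytest

from groupedscore.grouped_model import GroupedDataset, ModelParams


def brute_force_loglik(k, delta, Z, x, beta, theta, alpha):
    """Independent per-sample product evaluation of the grouped likelihood.

    Uses plain ``**`` arithmetic on the alpha scale, no log1p/expm1 tricks,
    so it is an independent oracle for the numerically-safe implementation.
    """
    total = 0.0
    for i in range(len(k)):
        w = np.exp(x[i] * beta + float(np.dot(Z[i], theta)))
        L = 1.0
        if delta[i] == 1:
            L *= 1.0 - alpha[k[i] - 1] ** w
        for j in range(k[i] - 1):
            L *= alpha[j] ** w
        total += np.log(L)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Random grouped dataset: n=20, r=4, q=2, with at least one event."""
    n, r, q = 20, 4, 2
    k = rng.integers(1, r + 1, n)
    delta = rng.integers(0, 2, n)
    delta[0] = 1
    Z = rng.standard_normal((n, q))
    x = rng.binomial(2, 0.3, n).astype(float)
    data = GroupedDataset(k, delta, Z, r=r)
    params = ModelParams(0.5, [0.3, -0.2], np.array([0.8, 0.7, 0.6, 0.5]))
    return data, x, params


@pytest.fixture(scope="session")
def null_cohort():
    """One simulated null cohort (beta=0) with its fitted nuisance model."""
    import warnings

    from groupedscore.null_fit import fit_null
    from groupedscore.simulate import SimulationConfig, simulate_grouped

    cfg = SimulationConfig(n=300, beta=0.0, maf=0.3, target_event_rate=0.5, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data, x, extras = simulate_grouped(cfg)
        eta = fit_null(data)
    return data, x, eta
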