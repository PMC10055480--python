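import numpy as np
import pytest

from sohpie import AbundanceTable, SimConfig, simulate_replicate


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_table(rng):
    """30 samples x 8 taxa of positive counts (no zeros)."""
    counts = rng.integers(1, 500, size=(30, 8))
    return AbundanceTable(counts)


@pytest.fixture(scope="session")
def tiny_replicate():
    """One small simulated data set shared across tests (p=10, n=60)."""
    cfg = SimConfig(p=10, n=60, setting="univariable", delta=0.2)
    return simulate_replicate(cfg, seed=7)


def lognormal_compositions(rng, n, p, sigma2=1.0, rho=None, pair=(0, 1)):
    """Compositions from independent log-normals, optionally one
    correlated pair with basis correlation ``rho`` (the test oracle for
    compositional correlation recovery)."""
    z = rng.standard_normal((n, p))
    if rho is not None:
        j, k = pair
        z[:, k] = rho * z[:, j] + np.sqrt(1 - rho**2) * z[:, k]
    log_abund = np.sqrt(sigma2) * z
    abund = np.exp(log_abund)
    return abund / abund.sum(axis=1, keepdims=True)
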