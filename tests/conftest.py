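import numpy as np
import pytest

from sgrn import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-gene, 100-sample synthetic dataset with moderate density."""
    return simulate_dataset(SimulationConfig(n_genes=10, n_samples=100,
                                             edges_per_gene=2.0, seed=7))


@pytest.fixture(scope="session")
def sparse_dataset():
    """A 10-gene, 200-sample synthetic dataset with one edge per gene."""
    return simulate_dataset(SimulationConfig(n_genes=10, n_samples=200,
                                             edges_per_gene=1.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def tiny_instance(seed, m_g=4, m_s=4, n=25):
    """Small centered (Y, X) pair for oracle comparisons."""
    r = np.random.default_rng(seed)
    ds = simulate_dataset(SimulationConfig(n_genes=max(m_g, m_s), n_samples=n,
                                           edges_per_gene=1.0, seed=seed))
    Yc = ds.Y.centered[:m_g]
    Xc = ds.X.centered[:m_s]
    return Yc, Xc
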