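import numpy as np
import pytest

from mgcna.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_config():
    """Small planted-block dataset config used by fast unit tests."""
    return SyntheticConfig(
        n_mirnas=30, n_drugs=12, n_genes=40, n_blocks=3,
        within_block_assoc_prob=0.5, cross_block_assoc_prob=0.05, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate(tiny_config).dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric_adjacency(rng, n, p=0.4):
    a = (rng.random((n, n)) < p).astype(float)
    a = ((a + a.T) > 0).astype(float)
    np.fill_diagonal(a, 1.0)
    return a
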