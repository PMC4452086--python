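import numpy as np
import pytest

from protolex import SparseSynthConfig, gen_sparse_vectors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_1000():
    """The 1000x1000 sparse synthetic benchmark matrix (98% zeros)."""
    return gen_sparse_vectors(SparseSynthConfig(seed=7))


@pytest.fixture(scope="session")
def synth_small():
    """A small sparse matrix for cheap projection tests."""
    return gen_sparse_vectors(
        SparseSynthConfig(n_vectors=60, dim=40, zero_probability=0.7, seed=3)
    )
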