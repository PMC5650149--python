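import numpy as np
import pytest

from netbin.core import WeightedNetwork


@pytest.fixture
def toy4():
    """4-node toy weight matrix: ab=0.9 ac=0.8 ad=0.1 bc=0.2 bd=0.3 cd=0.4."""
    from netbin.io import TOY_WEIGHTS_4

    return WeightedNetwork(TOY_WEIGHTS_4.copy())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weight_matrix(rng, n, low=0.05, high=0.95):
    """Random symmetric weight matrix with distinct off-diagonal entries."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    W[iu] = rng.uniform(low, high, size=iu[0].size)
    W += W.T
    return W
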