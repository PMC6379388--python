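import numpy as np
import pytest

from wormnet.fixtures import make_uniform_gas


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_gas():
    """Random 40-particle configuration in a 6x6 box (dense enough to interact)."""
    return make_uniform_gas(40, 6.0, seed=7)
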