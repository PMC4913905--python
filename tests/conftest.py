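import numpy as np
import pytest

from gsacc.simulate import GeneticMap, make_founders


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    return GeneticMap.equally_spaced(100)


@pytest.fixture
def founders(small_map):
    return make_founders(small_map)
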