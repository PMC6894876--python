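import numpy as np
import pytest

from grasscarbon.synthetic import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A seconds-scale synthetic spec shared across tests."""
    return SyntheticSpec(seed=7, shape=(20, 20), n_profiles=30, n_surveys=59)
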