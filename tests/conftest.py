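import numpy as np
import pytest

from plastarch.synthetic_data import hoya_like_spec, make_plastome


@pytest.fixture(scope="session")
def hoya_plastome():
    """One 1/10-scale ingroup-like plastome with its ground truth."""
    return make_plastome(hoya_like_spec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
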