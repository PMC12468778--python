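import numpy as np
import pytest

from demun import make_dct_model, make_gaussian_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["gaussian", "dct"])
def any_model(request):
    """A small operator of each kind (side=6, rate=0.5)."""
    if request.param == "gaussian":
        return make_gaussian_model(6, 0.5, seed=3)
    return make_dct_model(6, 0.5, pattern="uniform", seed=3)


@pytest.fixture
def random_trace(rng):
    """A length-T stack of random side x side images plus a ground truth."""
    def make(T=5, side=4):
        return [rng.random((side, side)) for _ in range(T)], rng.random((side, side))
    return make
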