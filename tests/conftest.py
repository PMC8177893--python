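import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, scale=1.0):
    M = rng.standard_normal((n, n))
    return scale * (M @ M.T + n * np.eye(n))


@pytest.fixture
def spd_factory(rng):
    def make(n=5, scale=1.0):
        return random_spd(rng, n, scale)

    return make
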