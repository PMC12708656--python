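import numpy as np
import pytest

from nematurb.model import ModelParams, make_grid


@pytest.fixture(scope="session")
def grid32():
    return make_grid(32)


@pytest.fixture(scope="session")
def grid64():
    return make_grid(64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def params_a500():
    return ModelParams(A=500.0)


def smooth_random_field(g, rng, amplitude=0.1, k_cut=4):
    """Band-limited random field used by equivariance/incompressibility
    property tests (smooth enough for spectral operations to be benign)."""
    from nematurb.initial import initial_condition

    return initial_condition("random_smooth", g, rng=rng, amplitude=amplitude,
                             k_cut=k_cut).theta
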