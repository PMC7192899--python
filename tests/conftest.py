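import numpy as np
import pytest

from semil.design_space import InputBounds, make_grid


@pytest.fixture(scope="session")
def bounds():
    return InputBounds(1.0, 2048.0)


@pytest.fixture(scope="session")
def small_grid(bounds):
    """A coarse design grid shared by landscape-level tests."""
    return make_grid(bounds, (2.0, 1024.0), (1.1, 30.0), 15, 15)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
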