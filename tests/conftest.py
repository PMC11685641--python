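import numpy as np
import pytest

from sohotspots.grid import build_grid


@pytest.fixture(scope="session")
def default_grid():
    """The production 9°x3° circumpolar grid (40 x 15 cells)."""
    return build_grid()


@pytest.fixture(scope="session")
def small_grid():
    """A coarse 8x3 grid for fast exhaustive checks."""
    return build_grid(45.0, 15.0, -45.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
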