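import numpy as np
import pytest

from spyrotrack.instrument import default_instrument
from spyrotrack.pose_grid import Box, GridSpec


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def workspace():
    return Box(lo=(-100.0,) * 3, hi=(100.0,) * 3)


@pytest.fixture(scope="session")
def small_spec():
    """A grid small enough for exhaustive oracle checks."""
    return GridSpec(
        rotation_base_shape=(2, 1, 2),
        position_base_shape=(2, 2, 2),
        max_level=1,
        top_k=None,
    )
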