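import numpy as np
import pytest

from fluordepth.grid import DEFAULT_GRID
from fluordepth.lut import build_lut


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def lut():
    """Shared 200x200 lookup table (build cost amortized over the session)."""
    return build_lut()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
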