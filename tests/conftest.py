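import numpy as np
import pytest

from cfskit.stimulus import DisplayGeometry


@pytest.fixture
def default_geometry() -> DisplayGeometry:
    """Canonical display: 7.32 deg bounding square rendered at 128 px."""
    return DisplayGeometry()


@pytest.fixture
def small_geometry() -> DisplayGeometry:
    """Tiny display for raster-level oracle tests (32 px frames)."""
    return DisplayGeometry(pixels_per_degree=32.0 / 7.32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
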