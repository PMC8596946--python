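import numpy as np
import pytest

from deltapls.io import MaskGeometry


@pytest.fixture
def small_geometry() -> MaskGeometry:
    """A 6x6x6 grid with a 3x3x3 cubic mask (27 voxels) at 3 mm."""
    mask = np.zeros((6, 6, 6), dtype=bool)
    mask[1:4, 1:4, 1:4] = True
    return MaskGeometry(mask=mask)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
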