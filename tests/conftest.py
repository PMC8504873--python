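import numpy as np
import pytest

from elastomics.conversion import ColorImage
from elastomics.roi import ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return ColorImage(rng.integers(0, 256, size=(24, 32, 3), dtype=np.uint8))


@pytest.fixture
def achromatic_image(rng):
    v = rng.integers(0, 256, size=(24, 32), dtype=np.uint8)
    return ColorImage(np.stack([v, v, v], axis=-1))


@pytest.fixture
def center_mask():
    """A 10x14 rectangular ROI inside a 24x32 frame."""
    m = np.zeros((24, 32), dtype=bool)
    m[7:17, 9:23] = True
    return ROIMask(m)
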