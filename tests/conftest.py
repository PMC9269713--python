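import numpy as np
import pytest

from mammocad.roi_prep import GrayROI, LesionClass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_roi(pixels, label=LesionClass.BENIGN, tag="orig"):
    return GrayROI(pixels=np.asarray(pixels, dtype=float), label=label,
                   source=("fix", (0, 0), tag))


@pytest.fixture
def blob_roi():
    """Low-contrast centered Gaussian blob on a mid-gray background."""
    side = 32
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    c = (side - 1) / 2
    rr2 = (yy - c) ** 2 + (xx - c) ** 2
    img = 0.45 + 0.1 * np.exp(-rr2 / (2 * 6.0**2))
    return make_roi(img)


@pytest.fixture
def textured_roi(rng):
    """Blob plus mild texture so all three pseudo-color channels differ."""
    side = 32
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    c = (side - 1) / 2
    rr2 = (yy - c) ** 2 + (xx - c) ** 2
    img = 0.4 + 0.15 * np.exp(-rr2 / (2 * 5.0**2))
    img = img + 0.02 * rng.standard_normal((side, side))
    return make_roi(np.clip(img, 0, 1))
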