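import numpy as np
import pytest

from astroquant.io import CalibratedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_image():
    return CalibratedImage(pixels=np.full((32, 32), 128.0), um_per_px=1.0)


def make_image(pixels, um_per_px=1.0):
    return CalibratedImage(pixels=np.asarray(pixels, dtype=float), um_per_px=um_per_px)
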