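import numpy as np
import pytest

from pbnrr.image_io import MaskImage, ScalarImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, origin=None, spacing=None, direction=None):
    pixels = np.asarray(pixels, dtype=float)
    d = pixels.ndim
    return ScalarImage(
        pixels,
        np.zeros(d) if origin is None else np.asarray(origin, float),
        np.ones(d) if spacing is None else np.asarray(spacing, float),
        np.eye(d) if direction is None else np.asarray(direction, float),
    )


def full_mask(shape, spacing=None):
    d = len(shape)
    return MaskImage(
        np.ones(shape), np.zeros(d),
        np.ones(d) if spacing is None else np.asarray(spacing, float), np.eye(d),
    )


@pytest.fixture
def textured_3d(rng):
    """Small textured 3D image with identity geometry."""
    from scipy import ndimage

    pix = ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)), 1.5)
    return make_image(pix)


@pytest.fixture
def textured_2d(rng):
    from scipy import ndimage

    pix = ndimage.gaussian_filter(rng.standard_normal((48, 48)), 2.0)
    return make_image(pix)
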