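import numpy as np
import pytest

from ihcquant.synthetic import BACKGROUND_RGB, color_for_luma


def uniform_image(height, width, rgb):
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:, :] = rgb
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_pair(rng):
    a = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    b = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    return a, b


@pytest.fixture
def background_image():
    return uniform_image(32, 32, BACKGROUND_RGB)


@pytest.fixture
def stained_disk_image():
    """160x160 background with a radius-40 disk of luma ~195 (inside the ER band)."""
    from skimage.draw import disk

    img = uniform_image(160, 160, BACKGROUND_RGB)
    rr, cc = disk((80, 80), 40)
    img[rr, cc] = color_for_luma(195.0)
    return img, rr.size
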