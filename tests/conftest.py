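import numpy as np
import pytest

from radsurv.io import ImageVolume, SegmentationMask
from radsurv.synthetic import PhantomSpec, make_phantom


def make_ball_mask(radius: int, spacing=(1.0, 1.0, 1.0), margin: int = 4) -> SegmentationMask:
    """Digitized ball of the given radius in voxels."""
    n = 2 * radius + 2 * margin + 1
    c = (n - 1) / 2
    z, y, x = np.meshgrid(*[np.arange(n) - c] * 3, indexing="ij")
    return SegmentationMask((x ** 2 + y ** 2 + z ** 2) <= radius ** 2, spacing=spacing)


@pytest.fixture(scope="session")
def ball_mask():
    return make_ball_mask


@pytest.fixture(scope="session")
def small_phantom():
    """A modest spiculated phantom reused across feature tests."""
    spec = PhantomSpec(
        shape=(20, 36, 36),
        radii_mm=(8.0, 9.0, 8.0),
        spiculation_amplitude=0.15,
        texture_variance_hu2=400.0,
        seed=11,
    )
    return make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_volume(shape=(8, 8, 8), value=50.0, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.full(shape, float(value)), spacing=spacing)


def box_mask(shape=(8, 8, 8), lo=2, hi=6, spacing=(1.0, 1.0, 1.0)) -> SegmentationMask:
    vox = np.zeros(shape, bool)
    vox[lo:hi, lo:hi, lo:hi] = True
    return SegmentationMask(vox, spacing=spacing)
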