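import numpy as np
import pytest

from robustrad import ImageVolume, Mask


def make_sphere_mask(radius_vox: float, shape=None,
                     spacing=(1.0, 1.0, 1.0), centre=None) -> Mask:
    if shape is None:
        n = int(2 * radius_vox + 5)
        shape = (n, n, n)
    if centre is None:
        centre = tuple((s - 1) / 2 for s in shape)
    zz, yy, xx = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip((zz, yy, xx), centre))
    return Mask(d2 <= radius_vox ** 2, spacing)


@pytest.fixture
def sphere_mask():
    """A 10-voxel-radius digital sphere on a 1 mm grid."""
    return make_sphere_mask(10)


@pytest.fixture
def sphere_pair(sphere_mask):
    """Image/mask pair: noisy soft-tissue background with a brighter sphere."""
    rng = np.random.default_rng(42)
    arr = 40.0 + rng.normal(0.0, 5.0, sphere_mask.shape)
    arr[sphere_mask.array] += 20.0
    return ImageVolume(arr, sphere_mask.spacing), sphere_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
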