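import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from symreg.grids import DisplacementField


def smooth_random_field(shape, amplitude, sigma, seed) -> DisplacementField:
    """Gaussian-smoothed random field rescaled to a peak vector magnitude."""
    rng = np.random.default_rng(seed)
    D = len(shape)
    v = rng.standard_normal((D,) + tuple(shape))
    for c in range(D):
        v[c] = gaussian_filter(v[c], sigma)
    mag = np.sqrt((v**2).sum(axis=0)).max()
    if amplitude == 0 or mag == 0:
        v[:] = 0.0
    else:
        v *= amplitude / mag
    return DisplacementField(v)


def interior(array: np.ndarray, margin: int = 1) -> np.ndarray:
    """Strip a boundary shell of ``margin`` voxels from every axis."""
    return array[tuple(slice(margin, -margin) for _ in range(array.ndim))]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def field_factory():
    return smooth_random_field
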