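import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def dense_nudft_matrix(coords, shape):
    """Explicit NUDFT matrix (oracle): rows exp(-2j*pi*k.x), centered voxels."""
    axes = [np.arange(s) - s // 2 for s in shape]
    x = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    return np.exp(-2j * np.pi * (np.asarray(coords) @ x.T))


@pytest.fixture
def small_instance(rng):
    """8^3 image, 200 random coords, dense oracle matrix."""
    shape = (8, 8, 8)
    coords = rng.uniform(-0.5, np.nextafter(0.5, 0), (200, 3))
    u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return shape, coords, u, dense_nudft_matrix(coords, shape)
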