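import numpy as np
import pytest

from ablaq.accs import ACCSVolume


def make_ball(radius, center=(0.0, 0.0, 0.0), size=64):
    """Digital ball on the ACCS grid: voxel centres within `radius` mm."""
    ax = np.arange(size) - size // 2
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    cx, cy, cz = center
    vox = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= radius**2
    return ACCSVolume(voxels=vox.astype(np.uint8))


def make_ellipsoid(a, b, c, center=(0.0, 0.0, 0.0), size=64):
    """Digital ellipsoid with semi-axes (a, b, c) along (i, j, k)."""
    ax = np.arange(size) - size // 2
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    cx, cy, cz = center
    vox = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    return ACCSVolume(voxels=vox.astype(np.uint8))


@pytest.fixture(scope="session")
def ball12():
    return make_ball(12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
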