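import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from immunorad import ImageVolume, VoxelMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sphere_mask(radius_vox: int, spacing=(1.0, 1.0, 1.0), pad: int = 4):
    """Digital sphere: voxel centres within radius (in voxel units)."""
    half = radius_vox + pad
    ax = np.arange(-half, half + 1, dtype=float)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return VoxelMask(zz ** 2 + yy ** 2 + xx ** 2 <= radius_vox ** 2, spacing)


def make_random_region(rng, shape=(6, 6, 6), levels=4, mask_p=0.8,
                       spacing=(1.0, 1.0, 1.0)):
    """Random quantized-style volume + mask for oracle comparisons."""
    vals = rng.integers(1, levels + 1, size=shape)
    mask = rng.uniform(size=shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return vals.astype(np.int64), mask


@pytest.fixture
def sphere20():
    return make_sphere_mask(20)


@pytest.fixture
def small_volume(rng):
    vals = rng.normal(50, 12, size=(12, 12, 12))
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[3:9, 3:9, 3:9] = True
    return vol, VoxelMask(mask, (1.0, 1.0, 1.0))
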