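import numpy as np
import pytest

from neurocovar.simulate import default_grid
from neurocovar.volume import BinaryMask, ScalarVolume, VolumeGrid


@pytest.fixture
def small_grid() -> VolumeGrid:
    """A tiny centered 2 mm isotropic grid for geometric tests."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -10.0  # 11 voxels per axis, centers at -10..10
    return VolumeGrid((11, 11, 11), affine)


@pytest.fixture
def template_grid() -> VolumeGrid:
    """Smallest grid on which all canonical seed/template geometry fits."""
    return default_grid((30, 36, 28), 4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def full_mask(grid: VolumeGrid) -> BinaryMask:
    return BinaryMask(grid, np.ones(grid.shape, dtype=bool))


def volume_from_flat(grid: VolumeGrid, flat: np.ndarray) -> ScalarVolume:
    return ScalarVolume(grid, np.asarray(flat, dtype=float).reshape(grid.shape))
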