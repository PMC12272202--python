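import numpy as np
import pytest

from vasconn.grid import BinaryMask, Bold4D, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_grid():
    return VolumeGrid.from_spacing((8, 8, 8), (4.0, 4.0, 4.0))


def make_bold(data, tr_s=2.2, voxel_mm=4.0):
    """Bold4D from a raw (x, y, z, t) array with an isotropic grid."""
    grid = VolumeGrid.from_spacing(data.shape[:3], (voxel_mm,) * 3)
    return Bold4D(grid, np.asarray(data, dtype=float), tr_s)


def mask_from_array(arr, voxel_mm=4.0):
    grid = VolumeGrid.from_spacing(arr.shape, (voxel_mm,) * 3)
    return BinaryMask(grid, np.asarray(arr, dtype=bool))


@pytest.fixture
def make_bold_fixture():
    return make_bold


@pytest.fixture
def make_mask():
    return mask_from_array
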