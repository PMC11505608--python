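import numpy as np
import pytest

from nucleomorph import SpatialCalibration


@pytest.fixture
def cal():
    """The default isotropic 0.25 µm calibration used by the phantoms."""
    return SpatialCalibration(pixel_size_xy=0.25, z_step=0.25)


@pytest.fixture
def unit_cal():
    """1 µm isotropic calibration: voxel indices equal physical coordinates."""
    return SpatialCalibration(pixel_size_xy=1.0, z_step=1.0)


def solid_ball_mask(shape, centre, radius_vox):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
            <= radius_vox**2)
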