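import numpy as np
import pytest

from petcompare import ImageGrid, InjectionRecord, RoiMask, VolumetricImage
from petcompare.pipeline import direction_of_effect_battery


@pytest.fixture
def unit_grid():
    """9x9x9 grid with 10 mm voxels: voxel volume exactly 1 cm^3."""
    return ImageGrid((9, 9, 9), (10.0, 10.0, 10.0))


@pytest.fixture
def cube_suv_image(unit_grid):
    """SUV 10 cube (3x3x3 voxels) in background SUV 1."""
    values = np.ones(unit_grid.size)
    values[3:6, 3:6, 3:6] = 10.0
    return VolumetricImage(unit_grid, values, "suv")


@pytest.fixture
def cube_mask(unit_grid):
    occ = np.zeros(unit_grid.size, bool)
    occ[3:6, 3:6, 3:6] = True
    return RoiMask(unit_grid, occ, "lesion")


@pytest.fixture
def full_search(unit_grid):
    return RoiMask(unit_grid, np.ones(unit_grid.size, bool), "search_region")


@pytest.fixture
def record():
    """Injection with zero uptake time: decay factor exactly 1."""
    return InjectionRecord(
        injected_dose_mbq=350.0,
        injection_time_s=0.0,
        scan_start_time_s=0.0,
        body_weight_g=70_000.0,
    )


@pytest.fixture(scope="session")
def battery():
    """Noiseless single-sphere phantom battery over 8-40 mm diameters.

    Session-scoped: several tests read different columns of the same run.
    """
    return direction_of_effect_battery(seed=0)
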