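"""Spatial agreement of MTVs across reconstructions: the classification error.

CE = (false-negative volume + false-positive volume) / reference volume,
where the false-negative volume is mask present on the reference but not on
the test, and vice versa for false-positive.  CE is 0 for perfect overlap and
unbounded above (2.0 for equal-volume disjoint masks).

Masks from two reconstructions live on different grids; both are resampled
(nearest-neighbour by voxel centre) onto the finer of the two grids before
voxel counting, so sub-voxel disagreement visible at the finer resolution is
not destroyed by the coarser rasterization.  All three volumes and the ratio
are measured on that comparison grid, keeping ce = (fn + fp) / ref exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import ImageGrid, RoiMask, resample_mask

__all__ = ["OverlapResult", "classification_error"]


@dataclass(frozen=True)
class OverlapResult:
    ce: float
    false_negative_cm3: float
    false_positive_cm3: float
    reference_volume_cm3: float
    comparison_grid: ImageGrid


def classification_error(reference: RoiMask, test: RoiMask) -> OverlapResult:
    """Classification error of ``test`` against ``reference``.

    Raises if the reference mask is empty (the denominator is undefined) or
    if the masks' world extents are disjoint.
    """
    if reference.is_empty():
        raise ValueError("reference mask is empty: classification error undefined")

    if reference.grid.approx_equal(test.grid):
        grid = reference.grid
        ref_occ, test_occ = reference.occupancy, test.occupancy
    else:
        # compare on the finer grid (smaller voxel volume)
        grid = min(reference.grid, test.grid, key=lambda g: g.voxel_volume_cm3)
        ref_occ = resample_mask(reference, grid).occupancy
        test_occ = resample_mask(test, grid).occupancy

    vv = grid.voxel_volume_cm3
    ref_vol = float(ref_occ.sum()) * vv
    if ref_vol == 0:
        raise ValueError(
            "reference mask is empty on the comparison grid (disjoint world extents?)"
        )
    fn = float(np.sum(ref_occ & ~test_occ)) * vv
    fp = float(np.sum(test_occ & ~ref_occ)) * vv
    return OverlapResult((fn + fp) / ref_vol, fn, fp, ref_vol, grid)
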