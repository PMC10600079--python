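"""Metabolic tumor volume (MTV) segmentation and total lesion glycolysis.

Nine threshold rules are supported, matching common clinical practice for
FDG-PET target definition in head-and-neck cancer:

* ``adaptive_sur`` -- an adaptive threshold expressed as a percentage of
  SUR_max: ``percent = 116.93 * SUR_max**-0.75``, i.e. an absolute SUR cut of
  ``1.1693 * SUR_max**0.25``, converted to SUV units via the cord mean.
* ``static_suv`` 2.5 / 3.5 / 4.5 -- absolute SUV cuts.
* ``static_sur`` 2.5 / 3.5 / 4.5 -- absolute SUR cuts (times the cord
  SUV_mean of the same reconstruction).
* ``percent_max`` 40 / 50 -- percentage of the lesion's SUV_max within the
  search region (MAX40%, MAX50%).

Segmentation is confined to a caller-supplied search region (in practice the
CT-based delineation): unconfined thresholding at e.g. SUV 2.5 would leak
into physiologic uptake.  The supra-threshold rule is closed (``>=``), so the
maximum voxel always belongs to its own percent-max mask.  TLG is defined for
SUV-based methods only (static SUV and percent-max cuts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_model import RoiMask, VolumetricImage
from .uptake import suv_max, suv_mean

__all__ = [
    "SegmentationMethod",
    "MtvResult",
    "standard_methods",
    "adaptive_threshold_percent",
    "segment_mtv",
    "tlg",
]

_KINDS = ("adaptive_sur", "static_suv", "static_sur", "percent_max")


@dataclass(frozen=True)
class SegmentationMethod:
    """One threshold rule: a kind plus its parameter (None for adaptive)."""

    kind: str
    parameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "adaptive_sur":
            if self.parameter is not None:
                raise ValueError("adaptive_sur takes no parameter")
        elif self.parameter is None or self.parameter <= 0:
            raise ValueError(f"{self.kind} requires a positive parameter")

    @property
    def uses_cord(self) -> bool:
        return self.kind in ("adaptive_sur", "static_sur")

    @property
    def has_tlg(self) -> bool:
        """TLG is computed for SUV-based cuts only (not SUR-based ones)."""
        return self.kind in ("static_suv", "percent_max")

    @property
    def name(self) -> str:
        if self.kind == "adaptive_sur":
            return "adaptive"
        if self.kind == "static_suv":
            return f"SUV{self.parameter:g}"
        if self.kind == "static_sur":
            return f"SUR{self.parameter:g}"
        return f"MAX{self.parameter:g}%"


def standard_methods() -> list[SegmentationMethod]:
    """The nine standard methods: adaptive, SUV/SUR 2.5/3.5/4.5, MAX40/50%."""
    methods = [SegmentationMethod("adaptive_sur")]
    methods += [SegmentationMethod("static_suv", p) for p in (2.5, 3.5, 4.5)]
    methods += [SegmentationMethod("static_sur", p) for p in (2.5, 3.5, 4.5)]
    methods += [SegmentationMethod("percent_max", p) for p in (40.0, 50.0)]
    return methods


def method_by_name(name: str) -> SegmentationMethod:
    for m in standard_methods():
        if m.name.lower() == name.lower():
            return m
    raise ValueError(f"unknown segmentation method {name!r}")


@dataclass
class MtvResult:
    """A segmented MTV: mask, volume, optional TLG and the cut that produced it."""

    mask: RoiMask
    mtv_cm3: float
    tlg_g: Optional[float]
    threshold_suv: float
    method: SegmentationMethod
    degenerate: bool = False


def adaptive_threshold_percent(sur_max_value: float) -> float:
    """Adaptive threshold as a percentage of SUR_max: ``116.93 * SUR_max**-0.75``.

    The caller converts this to an absolute SUR cut as
    ``percent / 100 * SUR_max``.  Values above 100% mean the cut exceeds the
    maximum voxel and the segmentation degenerates to an empty volume.
    """
    if sur_max_value <= 0:
        raise ValueError("SUR_max must be positive")
    return 116.93 * sur_max_value ** -0.75


def _largest_component(occ: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(occ, structure=np.ones((3, 3, 3), dtype=bool))
    if n <= 1:
        return occ
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def segment_mtv(
    image: VolumetricImage,
    search: RoiMask,
    method: SegmentationMethod,
    cord: Optional[RoiMask] = None,
    largest_component: bool = False,
) -> MtvResult:
    """Threshold the SUV image within a search region.

    The absolute SUV cut is derived per method kind (see module docstring);
    voxels in the search region with value >= cut form the MTV mask.  No
    connectivity constraint is applied unless ``largest_component`` is set
    (26-connectivity).  An empty mask (including adaptive percent > 100) is
    returned with ``mtv_cm3 = 0`` and the ``degenerate`` flag set.
    """
    if image.value_kind != "suv":
        raise ValueError(f"segment_mtv expects an SUV image, got {image.value_kind!r}")
    if method.uses_cord and cord is None:
        raise ValueError(f"method {method.name} requires a cord reference mask")

    peak = suv_max(image, search)
    degenerate = False
    if method.kind == "static_suv":
        cut = float(method.parameter)
    elif method.kind == "static_sur":
        cut = float(method.parameter) * suv_mean(image, cord)
    elif method.kind == "percent_max":
        cut = method.parameter / 100.0 * peak
    else:  # adaptive_sur
        cord_mean = suv_mean(image, cord)
        if cord_mean <= 0:
            raise ValueError("cord reference SUV_mean is non-positive")
        sur = peak / cord_mean
        percent = adaptive_threshold_percent(sur)
        cut = percent / 100.0 * sur * cord_mean  # = 1.1693 * sur**0.25 * cord_mean
        if percent > 100.0:
            degenerate = True

    occ = search.occupancy & (image.values >= cut)
    if degenerate:
        occ = np.zeros_like(occ)
    if largest_component and occ.any():
        occ = occ & _largest_component(occ)
    mask = RoiMask(image.grid, occ, "lesion")
    if mask.is_empty():
        degenerate = True

    mtv = mask.volume_cm3
    tlg_g = None
    if method.has_tlg:
        tlg_g = tlg(image, mask)
    return MtvResult(mask, mtv, tlg_g, cut, method, degenerate)


def tlg(image: VolumetricImage, mtv_mask: RoiMask) -> float:
    """Total lesion glycolysis: MTV (cm^3) times SUV_mean over the MTV, in g.

    Identically the sum of voxel SUVs times the voxel volume; 0 for an empty
    mask.
    """
    if not image.grid.approx_equal(mtv_mask.grid):
        raise ValueError("mask grid does not match image grid")
    if mtv_mask.is_empty():
        return 0.0
    return mtv_mask.volume_cm3 * suv_mean(image, mtv_mask)
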