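"""Dose prescription, decay correction, SUV conversion and SUR computation.

The standardized uptake value (SUV) normalizes a tissue activity
concentration by the decay-corrected injected dose per gram of body weight::

    SUV (g/cm^3) = activity (MBq/cm^3) / (dose_MBq * 2**(-dt / T_half)) * weight_g

with ``dt`` the time from injection to scan start in seconds.  The
standardized uptake ratio (SUR) further normalizes a lesion's SUV_max by the
mean SUV of a reference region -- here the cervical spinal cord -- which
cancels any global multiplicative error (dose calibration, weight, decay):
SUR is scale-invariant where SUV is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import RoiMask, VolumetricImage

F18_HALF_LIFE_S = 6586.2
"""Physical half-life of fluorine-18, seconds."""

__all__ = [
    "F18_HALF_LIFE_S",
    "InjectionRecord",
    "UptakeMetrics",
    "prescribed_dose",
    "decay_factor",
    "to_suv",
    "suv_max",
    "suv_mean",
    "sur_max",
    "activity_for_suv",
]


@dataclass(frozen=True)
class InjectionRecord:
    """Injected dose, timing and body weight feeding the SUV denominator.

    Times are seconds on any common clock (only the difference
    ``scan_start_time_s - injection_time_s`` enters the decay correction).
    """

    injected_dose_mbq: float
    injection_time_s: float
    scan_start_time_s: float
    body_weight_g: float
    half_life_s: float = F18_HALF_LIFE_S

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if self.scan_start_time_s < self.injection_time_s:
            raise ValueError("scan start precedes injection")

    @property
    def uptake_time_s(self) -> float:
        return self.scan_start_time_s - self.injection_time_s


@dataclass(frozen=True)
class UptakeMetrics:
    """Per-lesion uptake summary: SUV_max, SUR_max and the cord reference."""

    suv_max: float
    sur_max: float
    cord_suv_mean: float


def prescribed_dose(weight_kg: float, acquisition_min_per_bed: float) -> float:
    """Prescribed [18F]FDG dose in MBq: 7 (MBq*min/bed/kg) * weight / duration."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if acquisition_min_per_bed <= 0:
        raise ValueError("acquisition duration per bed position must be positive")
    return 7.0 * weight_kg / acquisition_min_per_bed


def decay_factor(record: InjectionRecord) -> float:
    """Residual fraction ``2**(-dt/T_half)`` of activity at scan start; in (0, 1]."""
    return float(2.0 ** (-record.uptake_time_s / record.half_life_s))


def to_suv(image: VolumetricImage, record: InjectionRecord) -> VolumetricImage:
    """Convert an activity-concentration image (MBq/cm^3) to SUV (g/cm^3).

    Each voxel becomes ``v / (dose * decay_factor) * body_weight_g``.  Refuses
    images that are not tagged as activity (guards against double conversion).
    """
    if image.value_kind != "activity":
        raise ValueError(
            f"to_suv expects an activity image, got value_kind={image.value_kind!r}"
        )
    scale = record.body_weight_g / (record.injected_dose_mbq * decay_factor(record))
    out = VolumetricImage(image.grid, image.values * scale, "suv", injection=record)
    return out


def activity_for_suv(suv: float, record: InjectionRecord) -> float:
    """Activity concentration (MBq/cm^3) that maps to a given SUV -- inverse of to_suv."""
    return suv * record.injected_dose_mbq * decay_factor(record) / record.body_weight_g


def _check_roi(image: VolumetricImage, roi: RoiMask, what: str = "roi") -> np.ndarray:
    if not image.grid.approx_equal(roi.grid):
        raise ValueError(
            f"{what} grid does not match image grid (no implicit resampling; "
            "use image_model.resample_mask first)"
        )
    if roi.is_empty():
        raise ValueError(f"{what} mask is empty")
    return image.values[roi.occupancy]


def suv_max(image: VolumetricImage, roi: RoiMask) -> float:
    """Maximum voxel value within the ROI (voxel-centre membership)."""
    return float(_check_roi(image, roi).max())


def suv_mean(image: VolumetricImage, roi: RoiMask) -> float:
    """Arithmetic mean of voxel values within the ROI."""
    return float(_check_roi(image, roi).mean())


def sur_max(image: VolumetricImage, lesion: RoiMask, cord: RoiMask) -> float:
    """Lesion SUV_max divided by the cord reference region's SUV_mean."""
    lesion_max = suv_max(image, lesion)
    cord_mean = suv_mean(image, cord)
    if cord_mean <= 0:
        raise ValueError("cord reference SUV_mean is non-positive; SUR undefined")
    return lesion_max / cord_mean
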