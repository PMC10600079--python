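"""Grids, volumetric images, ROI masks, and NIfTI round-trip I/O.

Conventions used throughout the package:

* World coordinates are millimetres on axis-aligned grids.  Voxel ``(i, j, k)``
  (0-based) occupies the half-open box ``[origin + index * spacing,
  origin + (index + 1) * spacing)`` and is sampled at its centre,
  ``origin + (index + 0.5) * spacing``.
* Volumes are reported in cm**3 (the unit clinical PET reports use), so
  ``voxel_volume_cm3 = prod(spacing_mm) / 1000``.
* Images carry a ``value_kind`` tag -- ``"activity"`` (MBq/cm**3), ``"suv"``
  (g/cm**3) or ``"sur"`` (unitless) -- so unit errors (e.g. thresholding an
  activity map with an SUV cut, or converting to SUV twice) fail loudly.
* Masks live on a named grid.  No operation resamples implicitly; cross-grid
  work must call :func:`resample_mask`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

VALUE_KINDS = ("activity", "suv", "sur")
MASK_LABELS = ("lesion", "cord", "search_region")

__all__ = [
    "ImageGrid",
    "VolumetricImage",
    "RoiMask",
    "voxel_centers_world",
    "resample_mask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class ImageGrid:
    """A regular, axis-aligned 3-D voxel grid in world (mm) coordinates."""

    size: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        size = tuple(int(s) for s in self.size)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(size) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("ImageGrid requires 3-element size, spacing and origin")
        if any(s <= 0 for s in size):
            raise ValueError(f"grid size must be positive, got {size}")
        if any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise ValueError(f"grid spacing must be positive, got {spacing}")
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.size

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.size[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world corners of the grid's extent."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.size, dtype=float) * np.asarray(self.spacing, dtype=float)
        return lo, hi

    def approx_equal(self, other: "ImageGrid", tol: float = 1e-9) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.spacing, other.spacing, atol=tol, rtol=0)
            and np.allclose(self.origin, other.origin, atol=tol, rtol=0)
        )


def voxel_centers_world(grid: ImageGrid) -> np.ndarray:
    """Array of shape ``(*grid.size, 3)`` with each voxel's centre in mm."""
    axes = [grid.axis_centers(a) for a in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _require_grid(grid) -> ImageGrid:
    if not isinstance(grid, ImageGrid):
        raise TypeError(f"expected ImageGrid, got {type(grid).__name__}")
    return grid


@dataclass
class VolumetricImage:
    """A scalar field on an :class:`ImageGrid` with a tagged value kind.

    Parameters
    ----------
    grid : ImageGrid
    values : ndarray, shape ``grid.size``
        Finite voxel values; must be non-negative for ``activity`` and
        ``suv`` kinds.
    value_kind : {"activity", "suv", "sur"}
    injection : InjectionRecord, optional
        Dose / timing / weight metadata needed for SUV conversion; ``None``
        when unknown (e.g. a NIfTI read without its JSON sidecar).
    """

    grid: ImageGrid
    values: np.ndarray
    value_kind: str
    injection: Optional[object] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        _require_grid(self.grid)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.size):
            raise ValueError(
                f"values shape {self.values.shape} != grid size {self.grid.size}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.value_kind in ("activity", "suv") and np.any(self.values < 0):
            raise ValueError(f"{self.value_kind} image contains negative values")

    def with_values(self, values: np.ndarray, value_kind: Optional[str] = None) -> "VolumetricImage":
        return VolumetricImage(
            self.grid, values, value_kind or self.value_kind, injection=self.injection
        )


@dataclass
class RoiMask:
    """Boolean voxel occupancy on a grid, labelled by role."""

    grid: ImageGrid
    occupancy: np.ndarray
    label: str = "lesion"

    def __post_init__(self) -> None:
        _require_grid(self.grid)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != tuple(self.grid.size):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != grid size {self.grid.size}"
            )
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}, got {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not self.occupancy.any()


def resample_mask(mask: RoiMask, target: ImageGrid) -> RoiMask:
    """Resample a mask onto ``target`` by nearest-neighbour voxel-centre lookup.

    Each target voxel is occupied iff its centre falls inside an occupied
    source voxel (half-open voxel extents).  Target voxels outside the source
    grid are unoccupied.  Raises if the two grids share no world extent.
    """
    src = mask.grid
    lo_s, hi_s = src.bounds()
    lo_t, hi_t = _require_grid(target).bounds()
    if np.any(hi_s <= lo_t) or np.any(hi_t <= lo_s):
        raise ValueError("source and target grids have no world overlap")
    if src.approx_equal(target):
        return RoiMask(target, mask.occupancy.copy(), mask.label)

    idx, valid = [], []
    for ax in range(3):
        centers = target.axis_centers(ax)
        i = np.floor((centers - src.origin[ax]) / src.spacing[ax]).astype(int)
        valid.append((i >= 0) & (i < src.size[ax]))
        idx.append(np.clip(i, 0, src.size[ax] - 1))
    occ = mask.occupancy[np.ix_(idx[0], idx[1], idx[2])]
    inside = valid[0][:, None, None] & valid[1][None, :, None] & valid[2][None, None, :]
    return RoiMask(target, occ & inside, mask.label)


# ---------------------------------------------------------------------------
# NIfTI I/O.  The NIfTI affine maps a voxel *index* to the world position of
# its centre, so our translation column is origin + 0.5 * spacing.
# ---------------------------------------------------------------------------


def _affine_from_grid(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.spacing)
    return aff


def _grid_from_affine(affine: np.ndarray, shape, path) -> ImageGrid:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6:
        raise ValueError(f"{path}: non-axis-aligned orientation is not supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(f"{path}: malformed header (non-positive voxel spacing)")
    origin = affine[:3, 3] - 0.5 * spacing
    return ImageGrid(tuple(int(s) for s in shape[:3]), tuple(spacing), tuple(origin))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_image(image: VolumetricImage, path) -> Path:
    """Write a :class:`VolumetricImage` as NIfTI-1 (float32) + JSON sidecar.

    The sidecar carries the injection record (if present) and the value kind.
    """
    path = Path(path)
    nii = nib.Nifti1Image(image.values.astype(np.float32), _affine_from_grid(image.grid))
    nib.save(nii, str(path))
    sidecar = {"value_kind": image.value_kind}
    if image.injection is not None:
        rec = image.injection
        sidecar.update(
            injected_dose_MBq=rec.injected_dose_mbq,
            injection_time=rec.injection_time_s,
            scan_start_time=rec.scan_start_time_s,
            body_weight_g=rec.body_weight_g,
            half_life_s=rec.half_life_s,
        )
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path, value_kind: Optional[str] = None) -> VolumetricImage:
    """Read a NIfTI image; parse the JSON sidecar into an injection record.

    A missing sidecar is not an error: the image is returned with
    ``injection=None`` (callers needing SUV conversion will fail loudly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nii = nib.load(str(path))
    grid = _grid_from_affine(nii.affine, nii.shape, path)
    values = np.asarray(nii.dataobj, dtype=float)

    injection = None
    kind = value_kind
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = kind or meta.get("value_kind")
        if "injected_dose_MBq" in meta:
            from .uptake import InjectionRecord  # local import: avoids cycle

            injection = InjectionRecord(
                injected_dose_mbq=meta["injected_dose_MBq"],
                injection_time_s=meta["injection_time"],
                scan_start_time_s=meta["scan_start_time"],
                body_weight_g=meta["body_weight_g"],
                half_life_s=meta.get("half_life_s", 6586.2),
            )
    return VolumetricImage(grid, values, kind or "activity", injection=injection)


def write_mask(mask: RoiMask, path) -> Path:
    path = Path(path)
    nii = nib.Nifti1Image(mask.occupancy.astype(np.uint8), _affine_from_grid(mask.grid))
    nii.header["descrip"] = f"label={mask.label}".encode()
    nib.save(nii, str(path))
    return path


def read_mask(path, label: Optional[str] = None) -> RoiMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nii = nib.load(str(path))
    grid = _grid_from_affine(nii.affine, nii.shape, path)
    if label is None:
        descrip = bytes(nii.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        label = descrip.split("label=", 1)[1] if "label=" in descrip else "lesion"
    occ = np.asarray(nii.dataobj) > 0.5
    return RoiMask(grid, occ, label)
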