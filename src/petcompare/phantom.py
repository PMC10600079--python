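"""Digital phantom: paired reconstructions of a known activity ground truth.

A high-resolution (<= 1 mm) activity map is built from simple geometry --
spherical lesions and a cylindrical cervical-cord reference region over a
uniform background inside a body ellipsoid.  Each "reconstruction" of that
truth is emulated by convolving with an isotropic Gaussian point-spread
function of a stated FWHM and block-mean resampling onto a clinical voxel
grid; the two default reconstructions use 7.5 mm FWHM on a 4.1 x 4.1 x 5.0 mm
grid and 4.3 mm FWHM on a 2.0 x 2.0 x 5.0 mm grid, i.e. a blurrier and a
sharper protocol of the same acquisition.  The mechanism of interest --
resolution-driven partial volume error and its effect on uptake metrics and
threshold segmentation -- is fully captured by this forward model; iterative
reconstruction itself is not simulated.

Optionally, zero-mean Gaussian noise with a standard deviation proportional
to the local value is added, with independent sub-streams per reconstruction
derived from a single integer seed.  The default is noiseless, which is what
the analytic property checks assume.

Rasterization rule everywhere: a voxel belongs to a shape iff its centre is
inside the shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .agreement import ScoreCrossTab
from .image_model import ImageGrid, RoiMask, VolumetricImage
from .uptake import InjectionRecord, activity_for_suv

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))

__all__ = [
    "Lesion",
    "CordSpec",
    "ReconSpec",
    "PhantomSpec",
    "PhantomPair",
    "default_injection",
    "default_recon_specs",
    "single_lesion_spec",
    "neck_phantom_spec",
    "build_activity_truth",
    "simulate_reconstruction",
    "make_reconstruction_pair",
    "table5_fixture",
]


@dataclass(frozen=True)
class Lesion:
    """A spherical lesion: centre (mm), diameter (mm), activity (MBq/cm^3)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    activity: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.activity < 0:
            raise ValueError("lesion activity must be non-negative")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class CordSpec:
    """Cervical-cord reference cylinder, axis parallel to z."""

    center_xy_mm: tuple[float, float]
    radius_mm: float
    activity: float
    z_range_mm: Optional[tuple[float, float]] = None  # None = full FOV extent

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("cord radius must be positive")
        if self.activity < 0:
            raise ValueError("cord activity must be non-negative")


@dataclass(frozen=True)
class ReconSpec:
    """One emulated reconstruction: PSF FWHM, voxel spacing, noise level."""

    psf_fwhm_mm: float
    spacing_mm: tuple[float, float, float]
    noise_sd: float = 0.0
    name: str = "recon"

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm <= 0:
            raise ValueError("PSF FWHM must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("reconstruction voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_injection() -> InjectionRecord:
    """Typical cohort injection: 178 MBq, 69 min uptake, 70 kg patient."""
    return InjectionRecord(
        injected_dose_mbq=178.0,
        injection_time_s=0.0,
        scan_start_time_s=69.0 * 60.0,
        body_weight_g=70_000.0,
    )


def default_recon_specs(noise_sd: float = 0.0) -> tuple[ReconSpec, ReconSpec]:
    """The harmonization-standard pair: 7.5 mm FWHM on a 4.1 x 4.1 x 5.0 mm
    grid (EARL1-like) and 4.3 mm FWHM on a 2.0 x 2.0 x 5.0 mm grid
    (EARL2-like)."""
    return (
        ReconSpec(7.5, (4.1, 4.1, 5.0), noise_sd, "earl1_like"),
        ReconSpec(4.3, (2.0, 2.0, 5.0), noise_sd, "earl2_like"),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a paired-reconstruction phantom experiment."""

    fov_mm: tuple[float, float, float]
    lesions: tuple[Lesion, ...]
    background_activity: float
    cord: Optional[CordSpec] = None
    truth_spacing_mm: float = 1.0
    recon_specs: tuple[ReconSpec, ReconSpec] = field(default_factory=default_recon_specs)
    injection: InjectionRecord = field(default_factory=default_injection)
    search_margin_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(self, "recon_specs", tuple(self.recon_specs))
        if self.background_activity < 0:
            raise ValueError("background activity must be non-negative")
        if not (0 < self.truth_spacing_mm <= 1.0):
            raise ValueError("truth spacing must be in (0, 1] mm")
        if len(self.recon_specs) != 2:
            raise ValueError("exactly two reconstruction specs are required")
        for rs in self.recon_specs:
            if min(rs.spacing_mm) <= self.truth_spacing_mm:
                raise ValueError(
                    "truth spacing must be strictly finer than both reconstruction grids"
                )
        fov = np.asarray(self.fov_mm)
        for i, les in enumerate(self.lesions):
            c, r = np.asarray(les.center_mm), les.radius_mm
            if np.any(c - r < 0) or np.any(c + r > fov):
                raise ValueError(f"lesion {i} (d={les.diameter_mm} mm) extends outside the FOV")
        for i in range(len(self.lesions)):
            for j in range(i + 1, len(self.lesions)):
                li, lj = self.lesions[i], self.lesions[j]
                gap = np.linalg.norm(np.subtract(li.center_mm, lj.center_mm))
                if gap < li.radius_mm + lj.radius_mm:
                    raise ValueError(f"lesions {i} and {j} overlap")

    def truth_grid(self) -> ImageGrid:
        ts = self.truth_spacing_mm
        size = tuple(int(round(f / ts)) for f in self.fov_mm)
        return ImageGrid(size, (ts, ts, ts), (0.0, 0.0, 0.0))

    def recon_grid(self, recon: ReconSpec) -> ImageGrid:
        # floor: the coarse grid never extends past the truth FOV, so every
        # coarse voxel receives truth samples during block-mean resampling
        size = tuple(max(1, int(f // s)) for f, s in zip(self.fov_mm, recon.spacing_mm))
        return ImageGrid(size, recon.spacing_mm, (0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# rasterization (voxel-centre-in-shape everywhere)
# ---------------------------------------------------------------------------


def _sphere_occupancy(grid: ImageGrid, center, radius: float) -> np.ndarray:
    dx2 = (grid.axis_centers(0) - center[0]) ** 2
    dy2 = (grid.axis_centers(1) - center[1]) ** 2
    dz2 = (grid.axis_centers(2) - center[2]) ** 2
    return (
        dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
    ) <= radius**2


def _cylinder_occupancy(grid: ImageGrid, cord: CordSpec, fov_z: float) -> np.ndarray:
    dx2 = (grid.axis_centers(0) - cord.center_xy_mm[0]) ** 2
    dy2 = (grid.axis_centers(1) - cord.center_xy_mm[1]) ** 2
    in_plane = (dx2[:, None, None] + dy2[None, :, None]) <= cord.radius_mm**2
    z0, z1 = cord.z_range_mm if cord.z_range_mm is not None else (0.0, fov_z)
    zc = grid.axis_centers(2)
    in_z = (zc >= z0) & (zc <= z1)
    return in_plane & in_z[None, None, :]


def _ellipsoid_occupancy(grid: ImageGrid, fov) -> np.ndarray:
    # body outline: axis-aligned ellipsoid filling 80% of the FOV, to give
    # the background finite support away from the FOV edge
    center = np.asarray(fov) / 2.0
    semi = 0.8 * np.asarray(fov) / 2.0
    u2 = ((grid.axis_centers(0) - center[0]) / semi[0]) ** 2
    v2 = ((grid.axis_centers(1) - center[1]) / semi[1]) ** 2
    w2 = ((grid.axis_centers(2) - center[2]) / semi[2]) ** 2
    return (u2[:, None, None] + v2[None, :, None] + w2[None, None, :]) <= 1.0


def build_activity_truth(spec: PhantomSpec) -> VolumetricImage:
    """High-resolution activity ground truth (MBq/cm^3).

    Background fills a body ellipsoid; the cord cylinder and then the lesion
    spheres overwrite it.
    """
    grid = spec.truth_grid()
    values = np.zeros(grid.size, dtype=float)
    if spec.background_activity > 0:
        values[_ellipsoid_occupancy(grid, spec.fov_mm)] = spec.background_activity
    if spec.cord is not None:
        values[_cylinder_occupancy(grid, spec.cord, spec.fov_mm[2])] = spec.cord.activity
    for les in spec.lesions:
        values[_sphere_occupancy(grid, les.center_mm, les.radius_mm)] = les.activity
    return VolumetricImage(grid, values, "activity", injection=spec.injection)


def _overlap_weights(src: ImageGrid, dst: ImageGrid, axis: int) -> np.ndarray:
    """(n_dst, n_src) matrix of interval-overlap lengths (mm) along one axis."""
    s_lo = src.origin[axis] + np.arange(src.size[axis]) * src.spacing[axis]
    s_hi = s_lo + src.spacing[axis]
    d_lo = dst.origin[axis] + np.arange(dst.size[axis]) * dst.spacing[axis]
    d_hi = d_lo + dst.spacing[axis]
    return np.clip(
        np.minimum(d_hi[:, None], s_hi[None, :]) - np.maximum(d_lo[:, None], s_lo[None, :]),
        0.0,
        None,
    )


def simulate_reconstruction(
    truth: VolumetricImage,
    psf_fwhm_mm: float,
    grid: ImageGrid,
    noise_sd: float = 0.0,
    seed=None,
) -> VolumetricImage:
    """Emulate one reconstruction: Gaussian PSF blur + block-mean resampling.

    The truth is convolved with an isotropic Gaussian of the stated FWHM
    (sigma = FWHM / 2.3548), then each target voxel takes the volume mean of
    the blurred field over its box (exact box-overlap weights, so a constant
    field stays constant and total activity is preserved wherever the target
    grid covers the truth).  If ``noise_sd > 0``,
    multiplicative Gaussian noise (SD = noise_sd x local value) is added,
    reproducible from ``seed`` (an int or a numpy Generator); negatives are
    clamped to zero.
    """
    if psf_fwhm_mm <= 0:
        raise ValueError("PSF FWHM must be positive")
    src = truth.grid
    if psf_fwhm_mm < min(src.spacing):
        warnings.warn(
            f"PSF FWHM {psf_fwhm_mm} mm is below the truth spacing {min(src.spacing)} mm: "
            "the point-spread function is under-resolved",
            stacklevel=2,
        )
    if grid.voxel_volume_cm3 < src.voxel_volume_cm3:
        raise ValueError("target grid must be coarser than the truth grid")

    sigma_vox = [psf_fwhm_mm * FWHM_TO_SIGMA / s for s in src.spacing]
    # edge replication keeps a constant field exactly constant; phantoms keep
    # activity well away from the FOV edge so no spurious mass enters
    blurred = ndimage.gaussian_filter(truth.values, sigma=sigma_vox, mode="nearest")

    # box-mean resample: each target voxel takes the exact volume average of
    # the (piecewise-constant) blurred field over its box, via separable
    # overlap-length weights -- mass-preserving wherever the target covers
    # the truth
    values = blurred
    for ax in range(3):
        w = _overlap_weights(src, grid, ax)
        cover = w.sum(axis=1)
        if np.any(cover <= 0):
            raise ValueError("target grid extends beyond the truth field of view")
        values = np.moveaxis(np.tensordot(w / grid.spacing[ax], values, axes=(1, ax)), 0, ax)

    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values = values * (1.0 + noise_sd * rng.standard_normal(values.shape))
        np.maximum(values, 0.0, out=values)
    return VolumetricImage(grid, values, "activity", injection=truth.injection)


@dataclass
class GridMasks:
    """Phantom geometry rasterized on one reconstruction grid."""

    lesions: list[RoiMask]
    searches: list[RoiMask]
    cord: Optional[RoiMask]


@dataclass
class PhantomPair:
    """Two reconstructions of one truth, with masks rasterized per grid."""

    spec: PhantomSpec
    truth: VolumetricImage
    recons: tuple[VolumetricImage, VolumetricImage]
    masks: tuple[GridMasks, GridMasks]

    @property
    def names(self) -> tuple[str, str]:
        return tuple(rs.name for rs in self.spec.recon_specs)


def _masks_on_grid(spec: PhantomSpec, grid: ImageGrid) -> GridMasks:
    lesions, searches = [], []
    for les in spec.lesions:
        lesions.append(RoiMask(grid, _sphere_occupancy(grid, les.center_mm, les.radius_mm), "lesion"))
        searches.append(
            RoiMask(
                grid,
                _sphere_occupancy(grid, les.center_mm, les.radius_mm + spec.search_margin_mm),
                "search_region",
            )
        )
    cord = None
    if spec.cord is not None:
        cord = RoiMask(grid, _cylinder_occupancy(grid, spec.cord, spec.fov_mm[2]), "cord")
    return GridMasks(lesions, searches, cord)


def make_reconstruction_pair(spec: PhantomSpec) -> PhantomPair:
    """Build the truth once and emulate both reconstructions from it.

    The two reconstructions share the acquisition (one truth) but get
    independent noise sub-streams derived from ``spec.seed``, so identical
    specs reproduce bit-identical outputs.
    """
    truth = build_activity_truth(spec)
    children = np.random.SeedSequence(spec.seed).spawn(2)
    recons, masks = [], []
    for rs, child in zip(spec.recon_specs, children):
        grid = spec.recon_grid(rs)
        recons.append(
            simulate_reconstruction(
                truth, rs.psf_fwhm_mm, grid, rs.noise_sd, seed=np.random.default_rng(child)
            )
        )
        masks.append(_masks_on_grid(spec, grid))
    return PhantomPair(spec, truth, tuple(recons), tuple(masks))


# ---------------------------------------------------------------------------
# convenience phantom factories (the package's standard study conditions)
# ---------------------------------------------------------------------------

TRUTH_LESION_SUV = 12.0
TRUTH_BACKGROUND_SUV = 1.0
TRUTH_CORD_SUV = 1.6


def _standard_activities(injection: InjectionRecord):
    return (
        activity_for_suv(TRUTH_LESION_SUV, injection),
        activity_for_suv(TRUTH_BACKGROUND_SUV, injection),
        activity_for_suv(TRUTH_CORD_SUV, injection),
    )


def single_lesion_spec(
    diameter_mm: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    lesion_suv: float = TRUTH_LESION_SUV,
) -> PhantomSpec:
    """One sphere of the given diameter with a cord reference, for the
    partial-volume battery.

    The lesion centre sits on a coarse-grid voxel centre of the blurrier
    reconstruction so that peak sampling is aligned identically across
    diameters.  Truth contrast is lesion SUV 12 : background 1 : cord 1.6.
    """
    injection = default_injection()
    lesion_act = activity_for_suv(lesion_suv, injection)
    _, bg_act, cord_act = _standard_activities(injection)
    # (14.5)*4.1 = 59.45 in-plane, (9.5)*5.0 = 47.5 axial: voxel centres of
    # the 4.1 x 4.1 x 5.0 mm grid
    center = (59.45, 59.45, 47.5)
    return PhantomSpec(
        fov_mm=(120.0, 120.0, 100.0),
        lesions=(Lesion(center, diameter_mm, lesion_act),),
        background_activity=bg_act,
        cord=CordSpec((20.0, 59.45), 5.0, cord_act, z_range_mm=(30.0, 70.0)),
        recon_specs=default_recon_specs(noise_sd),
        injection=injection,
        seed=seed,
    )


def neck_phantom_spec(noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Multi-lesion phantom: six spheres, 8-40 mm, plus a cord reference."""
    injection = default_injection()
    lesion_act, bg_act, cord_act = _standard_activities(injection)
    diameters = (8.0, 12.0, 16.0, 24.0, 32.0, 40.0)
    xs = (47.15, 116.85, 182.45)  # voxel centres of the 4.1 mm grid
    ys = (55.35, 104.55)
    centers = [(x, y, 47.5) for y in ys for x in xs]
    lesions = tuple(
        Lesion(c, d, lesion_act) for c, d in zip(centers, diameters)
    )
    return PhantomSpec(
        fov_mm=(240.0, 160.0, 100.0),
        lesions=lesions,
        background_activity=bg_act,
        cord=CordSpec((120.0, 20.0), 5.0, cord_act, z_range_mm=(30.0, 70.0)),
        recon_specs=default_recon_specs(noise_sd),
        injection=injection,
        seed=seed,
    )


def table5_fixture() -> ScoreCrossTab:
    """Packaged 4x4 cross-tabulation of lymph-node visual scores.

    Rows are the score (1-4) on the blurrier reconstruction, columns the
    score on the sharper one; 175 nodes in total.
    """
    return ScoreCrossTab(
        np.array(
            [
                [75, 17, 1, 0],
                [3, 15, 11, 0],
                [0, 0, 15, 6],
                [0, 0, 0, 32],
            ]
        )
    )
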