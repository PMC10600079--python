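"""YAML config schema for phantom runs.

Activities may be given either directly (``activity``, MBq/cm^3) or as target
SUVs (``suv``), which are converted through the injection record.  Example::

    seed: 0
    fov_mm: [120, 120, 100]
    truth_spacing_mm: 1.0
    background_suv: 1.0
    search_margin_mm: 10.0
    injection: {dose_mbq: 178.0, uptake_min: 69.0, weight_kg: 70.0}
    cord: {center_xy_mm: [20.0, 59.45], radius_mm: 5.0, suv: 1.6,
           z_range_mm: [30.0, 70.0]}
    lesions:
      - {center_mm: [59.45, 59.45, 47.5], diameter_mm: 16.0, suv: 12.0}
    recons:
      - {name: earl1_like, psf_fwhm_mm: 7.5, spacing_mm: [4.1, 4.1, 5.0], noise_sd: 0.0}
      - {name: earl2_like, psf_fwhm_mm: 4.3, spacing_mm: [2.0, 2.0, 5.0], noise_sd: 0.0}
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .phantom import CordSpec, Lesion, PhantomSpec, ReconSpec, default_recon_specs
from .uptake import InjectionRecord, activity_for_suv

__all__ = ["load_phantom_config"]


def _injection(cfg: dict) -> InjectionRecord:
    inj = cfg.get("injection", {})
    return InjectionRecord(
        injected_dose_mbq=float(inj.get("dose_mbq", 178.0)),
        injection_time_s=0.0,
        scan_start_time_s=60.0 * float(inj.get("uptake_min", 69.0)),
        body_weight_g=1000.0 * float(inj.get("weight_kg", 70.0)),
        half_life_s=float(inj.get("half_life_s", 6586.2)),
    )


def _activity(entry: dict, injection: InjectionRecord, what: str) -> float:
    if "activity" in entry:
        return float(entry["activity"])
    if "suv" in entry:
        return activity_for_suv(float(entry["suv"]), injection)
    raise ValueError(f"{what}: provide either 'activity' (MBq/cm^3) or 'suv'")


def load_phantom_config(path, seed: Optional[int] = None) -> PhantomSpec:
    """Parse a YAML phantom config into a :class:`PhantomSpec`.

    ``seed`` overrides the file's seed when given.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    injection = _injection(cfg)

    lesions = tuple(
        Lesion(tuple(les["center_mm"]), float(les["diameter_mm"]), _activity(les, injection, "lesion"))
        for les in cfg.get("lesions", [])
    )

    cord = None
    if "cord" in cfg:
        c = cfg["cord"]
        cord = CordSpec(
            center_xy_mm=tuple(c["center_xy_mm"]),
            radius_mm=float(c["radius_mm"]),
            activity=_activity(c, injection, "cord"),
            z_range_mm=tuple(c["z_range_mm"]) if "z_range_mm" in c else None,
        )

    if "recons" in cfg:
        recons = tuple(
            ReconSpec(
                psf_fwhm_mm=float(r["psf_fwhm_mm"]),
                spacing_mm=tuple(r["spacing_mm"]),
                noise_sd=float(r.get("noise_sd", 0.0)),
                name=str(r.get("name", f"recon{i}")),
            )
            for i, r in enumerate(cfg["recons"])
        )
    else:
        recons = default_recon_specs(float(cfg.get("noise_sd", 0.0)))

    if "background_activity" in cfg:
        bg = float(cfg["background_activity"])
    else:
        bg = activity_for_suv(float(cfg.get("background_suv", 1.0)), injection)

    return PhantomSpec(
        fov_mm=tuple(cfg["fov_mm"]),
        lesions=lesions,
        background_activity=bg,
        cord=cord,
        truth_spacing_mm=float(cfg.get("truth_spacing_mm", 1.0)),
        recon_specs=recons,
        injection=injection,
        search_margin_mm=float(cfg.get("search_margin_mm", 10.0)),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
    )
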