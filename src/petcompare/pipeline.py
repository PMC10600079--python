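"""End-to-end comparison of two reconstructions of one acquisition.

``run_comparison`` chains the stages: phantom generation (or user-supplied
images), SUV conversion, per-lesion uptake metrics, nine-method MTV
segmentation, TLG, cross-reconstruction classification error, and agreement
statistics, and aggregates them into report tables (median + IQR of paired
per-lesion differences, percentages in reference to reconstruction A).

``direction_of_effect_battery`` runs the noiseless single-sphere phantom over
a range of diameters and collects, per diameter and method, the uptake and
MTV differences between the sharper and the blurrier reconstruction -- the
standard check that the simulator reproduces the expected partial-volume
behaviour (uptake gain largest for small lesions; volume shrinking for
relative thresholds and growing for static thresholds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import phantom as ph
from .agreement import (
    PairedSeries,
    ScoreCrossTab,
    bland_altman,
    cohen_kappa,
    icc_absolute_agreement,
    paired_tests,
    relative_differences,
    transition_analysis,
)
from .image_model import write_image, write_mask
from .overlap import classification_error
from .segmentation import SegmentationMethod, segment_mtv, standard_methods
from .uptake import suv_max, suv_mean, sur_max, to_suv

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "summarize",
    "run_comparison",
    "direction_of_effect_battery",
]


def summarize(values: Sequence[float], mode: str = "median") -> tuple[float, tuple[float, float]]:
    """Median with IQR (25th/75th percentile, linear interpolation), or
    mean with a 1.96*SE normal 95% CI when ``mode="mean"``."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty series")
    if mode == "median":
        q25, q50, q75 = np.percentile(arr, [25, 50, 75])
        return float(q50), (float(q25), float(q75))
    if mode == "mean":
        m = float(arr.mean())
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return m, (m - 1.96 * se, m + 1.96 * se)
    raise ValueError(f"mode must be 'median' or 'mean', got {mode!r}")


@dataclass
class RunConfig:
    """Configuration of one comparison run (phantom route)."""

    phantom_spec: ph.PhantomSpec
    methods: list[SegmentationMethod] = field(default_factory=standard_methods)
    paired_test: str = "wilcoxon"
    ba_mode: str = "mean_of_pair"
    score_crosstab: Optional[ScoreCrossTab] = None
    output_dir: Optional[Path] = None
    write_images: bool = False

    def __post_init__(self) -> None:
        if not self.phantom_spec.lesions:
            raise ValueError("the phantom needs at least one lesion")
        if not self.methods:
            raise ValueError("the methods list is empty")


@dataclass
class ComparisonReport:
    """All per-lesion and aggregated tables of one comparison run."""

    uptake: pd.DataFrame  # per lesion: SUV_max / SUR_max on A and B + % diffs
    mtv_per_lesion: pd.DataFrame  # long: lesion x method, MTV/TLG on A and B, CE
    mtv_summary: pd.DataFrame  # per method: median MTV A/B, paired diffs, p
    tlg_summary: pd.DataFrame  # per method (SUV-based only)
    ce_summary: pd.DataFrame  # per method: median CE / FN / FP
    uptake_agreement: pd.DataFrame  # ICC + Bland-Altman for SUV_max / SUR_max
    transitions: Optional[pd.DataFrame]
    names: tuple[str, str]
    seed: int

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.uptake.to_csv(outdir / "uptake_per_lesion.csv", index=False)
        self.mtv_per_lesion.to_csv(outdir / "mtv_per_lesion.csv", index=False)
        self.mtv_summary.to_csv(outdir / "mtv_summary.csv", index=False)
        self.tlg_summary.to_csv(outdir / "tlg_summary.csv", index=False)
        self.ce_summary.to_csv(outdir / "ce_summary.csv", index=False)
        self.uptake_agreement.to_csv(outdir / "uptake_agreement.csv", index=False)
        if self.transitions is not None:
            self.transitions.to_csv(outdir / "score_transitions.csv", index=False)
        return outdir


def _fmt_iqr(summary: tuple[float, tuple[float, float]]) -> tuple[float, float, float]:
    med, (lo, hi) = summary
    return med, lo, hi


def _method_rows(pair: ph.PhantomPair, suv_images, methods):
    """Segment every lesion with every method on both reconstructions."""
    rows = []
    for li in range(len(pair.spec.lesions)):
        for method in methods:
            res = []
            for side in (0, 1):
                res.append(
                    segment_mtv(
                        suv_images[side],
                        pair.masks[side].searches[li],
                        method,
                        cord=pair.masks[side].cord,
                    )
                )
            ra, rb = res
            row = {
                "lesion": li,
                "diameter_mm": pair.spec.lesions[li].diameter_mm,
                "method": method.name,
                "mtv_a_cm3": ra.mtv_cm3,
                "mtv_b_cm3": rb.mtv_cm3,
                "tlg_a_g": ra.tlg_g,
                "tlg_b_g": rb.tlg_g,
                "threshold_a_suv": ra.threshold_suv,
                "threshold_b_suv": rb.threshold_suv,
                "degenerate": ra.degenerate or rb.degenerate,
            }
            if not ra.degenerate and not rb.degenerate:
                ov = classification_error(ra.mask, rb.mask)
                row.update(
                    ce=ov.ce,
                    false_negative_cm3=ov.false_negative_cm3,
                    false_positive_cm3=ov.false_positive_cm3,
                )
            else:
                row.update(ce=np.nan, false_negative_cm3=np.nan, false_positive_cm3=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Run the full pipeline on a phantom spec; deterministic given its seed.

    Degenerate segmentations (empty MTV on either reconstruction) are
    excluded from the method medians and paired tests but counted in the
    summary tables.
    """
    spec = config.phantom_spec
    pair = ph.make_reconstruction_pair(spec)
    suv_images = tuple(to_suv(img, spec.injection) for img in pair.recons)

    # --- per-lesion uptake metrics -------------------------------------
    up_rows = []
    for li, les in enumerate(spec.lesions):
        row = {"lesion": li, "diameter_mm": les.diameter_mm}
        for side, tag in ((0, "a"), (1, "b")):
            img, masks = suv_images[side], pair.masks[side]
            row[f"suv_max_{tag}"] = suv_max(img, masks.lesions[li])
            row[f"sur_max_{tag}"] = sur_max(img, masks.lesions[li], masks.cord)
            row[f"cord_suv_mean_{tag}"] = suv_mean(img, masks.cord)
        row["suv_max_diff_pct"] = 100 * (row["suv_max_b"] - row["suv_max_a"]) / row["suv_max_a"]
        row["sur_max_diff_pct"] = 100 * (row["sur_max_b"] - row["sur_max_a"]) / row["sur_max_a"]
        up_rows.append(row)
    uptake = pd.DataFrame(up_rows)

    # --- uptake agreement stats ----------------------------------------
    agg_rows = []
    for metric in ("suv_max", "sur_max"):
        series = PairedSeries(
            tuple(uptake["lesion"]), uptake[f"{metric}_a"].to_numpy(), uptake[f"{metric}_b"].to_numpy()
        )
        row = {"metric": metric, "n": len(series)}
        if len(series) >= 3:
            try:
                icc, (lo, hi) = icc_absolute_agreement(series)
                row.update(icc=icc, icc_ci_low=lo, icc_ci_high=hi)
            except ValueError:
                row.update(icc=np.nan, icc_ci_low=np.nan, icc_ci_high=np.nan)
        bias, lo, hi = bland_altman(series)
        row.update(ba_bias_pct=bias, ba_low_pct=lo, ba_high_pct=hi)
        stat, p = paired_tests(series, config.paired_test)
        row.update(test=config.paired_test, statistic=stat, p_value=p)
        med, (q25, q75) = summarize(relative_differences(series, "reference_a"))
        row.update(median_diff_pct=med, diff_pct_q25=q25, diff_pct_q75=q75)
        agg_rows.append(row)
    uptake_agreement = pd.DataFrame(agg_rows)

    # --- segmentation / TLG / CE ---------------------------------------
    per_lesion = _method_rows(pair, suv_images, config.methods)

    mtv_rows, tlg_rows, ce_rows = [], [], []
    for method in config.methods:
        sub = per_lesion[per_lesion["method"] == method.name]
        ok = sub[~sub["degenerate"]]
        n_deg = int(sub["degenerate"].sum())
        row = {"method": method.name, "n": len(ok), "n_degenerate": n_deg}
        if len(ok):
            med_a, a25, a75 = _fmt_iqr(summarize(ok["mtv_a_cm3"]))
            med_b, b25, b75 = _fmt_iqr(summarize(ok["mtv_b_cm3"]))
            diffs = ok["mtv_b_cm3"] - ok["mtv_a_cm3"]
            pct = 100 * diffs / ok["mtv_a_cm3"]
            med_d, d25, d75 = _fmt_iqr(summarize(diffs))
            med_p, p25, p75 = _fmt_iqr(summarize(pct))
            row.update(
                median_mtv_a_cm3=med_a, mtv_a_q25=a25, mtv_a_q75=a75,
                median_mtv_b_cm3=med_b, mtv_b_q25=b25, mtv_b_q75=b75,
                median_diff_cm3=med_d, diff_q25=d25, diff_q75=d75,
                median_diff_pct=med_p, diff_pct_q25=p25, diff_pct_q75=p75,
            )
            if len(ok) >= 2 and not np.allclose(diffs, 0):
                series = PairedSeries(tuple(ok["lesion"]), ok["mtv_a_cm3"].to_numpy(), ok["mtv_b_cm3"].to_numpy())
                stat, p = paired_tests(series, config.paired_test)
                row.update(statistic=stat, p_value=p)
        mtv_rows.append(row)

        if method.has_tlg and len(ok):
            diffs = ok["tlg_b_g"] - ok["tlg_a_g"]
            pct = 100 * diffs / ok["tlg_a_g"]
            med_a, _, _ = _fmt_iqr(summarize(ok["tlg_a_g"]))
            med_b, _, _ = _fmt_iqr(summarize(ok["tlg_b_g"]))
            med_d, d25, d75 = _fmt_iqr(summarize(diffs))
            med_p, p25, p75 = _fmt_iqr(summarize(pct))
            tlg_rows.append(
                {
                    "method": method.name, "n": len(ok),
                    "median_tlg_a_g": med_a, "median_tlg_b_g": med_b,
                    "median_diff_g": med_d, "diff_g_q25": d25, "diff_g_q75": d75,
                    "median_diff_pct": med_p, "diff_pct_q25": p25, "diff_pct_q75": p75,
                }
            )

        ce_ok = sub.dropna(subset=["ce"])
        if len(ce_ok):
            med_ce, c25, c75 = _fmt_iqr(summarize(ce_ok["ce"]))
            med_fn, _, _ = _fmt_iqr(summarize(ce_ok["false_negative_cm3"]))
            med_fp, _, _ = _fmt_iqr(summarize(ce_ok["false_positive_cm3"]))
            ce_rows.append(
                {
                    "method": method.name, "n": len(ce_ok),
                    "median_ce": med_ce, "ce_q25": c25, "ce_q75": c75,
                    "median_fn_cm3": med_fn, "median_fp_cm3": med_fp,
                }
            )

    transitions = None
    if config.score_crosstab is not None:
        tr = transition_analysis(config.score_crosstab)
        trows = []
        for i in range(4):
            for j in range(4):
                trows.append(
                    {
                        "score_a": i + 1,
                        "score_b": j + 1,
                        "count": int(config.score_crosstab.counts[i, j]),
                        "row_proportion": tr.row_proportions[i, j],
                    }
                )
        transitions = pd.DataFrame(trows)
        transitions.attrs["upstaged"] = tr.upstaged
        transitions.attrs["downstaged"] = tr.downstaged
        transitions.attrs["kappa_dichotomized"] = cohen_kappa(config.score_crosstab, dichotomize=True)

    report = ComparisonReport(
        uptake=uptake,
        mtv_per_lesion=per_lesion,
        mtv_summary=pd.DataFrame(mtv_rows),
        tlg_summary=pd.DataFrame(tlg_rows),
        ce_summary=pd.DataFrame(ce_rows),
        uptake_agreement=uptake_agreement,
        transitions=transitions,
        names=pair.names,
        seed=spec.seed,
    )
    if config.output_dir is not None:
        outdir = report.write(config.output_dir)
        if config.write_images:
            write_image(pair.truth, outdir / "truth_activity.nii.gz")
            for side, tag in ((0, "a"), (1, "b")):
                write_image(pair.recons[side], outdir / f"recon_{tag}_activity.nii.gz")
                write_image(suv_images[side], outdir / f"recon_{tag}_suv.nii.gz")
                gm = pair.masks[side]
                for li, m in enumerate(gm.lesions):
                    write_mask(m, outdir / f"lesion{li}_{tag}.nii.gz")
                if gm.cord is not None:
                    write_mask(gm.cord, outdir / f"cord_{tag}.nii.gz")
        meta = {"seed": spec.seed, "names": list(pair.names), "n_lesions": len(spec.lesions)}
        (outdir / "run_meta.json").write_text(json.dumps(meta, indent=1))
    return report


def direction_of_effect_battery(
    diameters: Sequence[float] = (8.0, 12.0, 16.0, 24.0, 32.0, 40.0),
    methods: Optional[list[SegmentationMethod]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Noiseless single-sphere phantoms across diameters; long-format results.

    One row per (diameter, method) with SUV_max / SUR_max on both
    reconstructions, their % differences, MTVs, the paired MTV difference and
    the classification error.  The uptake columns repeat across methods of
    the same diameter for convenience.
    """
    methods = methods or standard_methods()
    rows = []
    for d in diameters:
        spec = ph.single_lesion_spec(d, seed=seed)
        pair = ph.make_reconstruction_pair(spec)
        suv_images = tuple(to_suv(img, spec.injection) for img in pair.recons)
        ups = {}
        for side, tag in ((0, "a"), (1, "b")):
            img, masks = suv_images[side], pair.masks[side]
            ups[f"suv_max_{tag}"] = suv_max(img, masks.lesions[0])
            ups[f"sur_max_{tag}"] = sur_max(img, masks.lesions[0], masks.cord)
        ups["suv_max_diff_pct"] = 100 * (ups["suv_max_b"] - ups["suv_max_a"]) / ups["suv_max_a"]
        ups["sur_max_diff_pct"] = 100 * (ups["sur_max_b"] - ups["sur_max_a"]) / ups["sur_max_a"]
        per_lesion = _method_rows(pair, suv_images, methods)
        for _, r in per_lesion.iterrows():
            row = {"diameter_mm": d, **ups, **r.drop(["lesion", "diameter_mm"]).to_dict()}
            if not row["degenerate"]:
                row["mtv_diff_pct"] = 100 * (row["mtv_b_cm3"] - row["mtv_a_cm3"]) / row["mtv_a_cm3"]
            else:
                row["mtv_diff_pct"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
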