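# petcompare

Quantitative comparison of two reconstructions of the same [18F]FDG PET
acquisition, for radiation-oncology and nuclear-medicine image analysis.

Modern harmonization standards (EARL) admit two reconstruction protocols of
different sharpness: an older one (7.5 mm FWHM Gaussian post-filter on a
4.1 × 4.1 × 5.0 mm grid) and a newer one (4.3 mm FWHM on 2.0 × 2.0 × 5.0 mm).
Because the partial-volume effect shrinks measured peak uptake in lesions
small relative to the scanner resolution, the sharper protocol reports higher
SUV_max — most strongly for small lymph nodes — which can flip threshold-based
tumor segmentations, inflate total lesion glycolysis, and upstage nodal
disease.  This package quantifies those effects end to end:

- **Uptake metrics** — SUV (activity normalized by decay-corrected injected
  dose per gram body weight, `SUV = c / (D · 2^(−Δt/T½)) · w`), and SUR
  (lesion SUV_max over the cervical-cord reference SUV_mean, which cancels
  global calibration errors).
- **Nine MTV segmentation methods** — an adaptive threshold
  (`percent = 116.93 · SUR_max^−0.75`), static SUV and SUR cuts
  (2.5 / 3.5 / 4.5), and percent-of-maximum cuts (MAX40%, MAX50%), confined
  to a search region; TLG = MTV · SUV_mean for the SUV-based methods.
- **Spatial overlap** — the classification error
  `CE = (FN + FP) / V_reference` between MTVs of the two reconstructions,
  computed on the finer voxel grid.
- **Agreement statistics** — relative differences (tabulation and
  Bland–Altman conventions), limits of agreement, a single-measure two-way
  ICC testing absolute agreement with F-based confidence interval, paired
  t / exact Wilcoxon signed-rank tests, Cohen's kappa and a visual-score
  transition analysis across the benign/malignant (score 2|3) boundary.
- **A digital phantom** — spherical lesions, a cord cylinder and a body
  ellipsoid on a ≤ 1 mm ground-truth grid; each reconstruction is emulated
  by Gaussian PSF convolution plus exact box-mean downsampling, with optional
  multiplicative noise.  Every stage is therefore verifiable against known
  ground truth without clinical data.

## Worked example

```python
from petcompare import RunConfig, run_comparison, table5_fixture
from petcompare.phantom import neck_phantom_spec

report = run_comparison(RunConfig(phantom_spec=neck_phantom_spec(),
                                  score_crosstab=table5_fixture()))
print(report.uptake[["diameter_mm", "suv_max_a", "suv_max_b",
                     "suv_max_diff_pct", "sur_max_diff_pct"]].round(2))
```

On the default six-sphere neck phantom (8–40 mm lesions, truth contrast
12 : 1 over background, cord SUV 1.6, noiseless) this prints:

```
 diameter_mm  suv_max_a  suv_max_b  suv_max_diff_pct  sur_max_diff_pct
         8.0       4.10       8.80            114.82             75.97
        12.0       7.73      11.60             49.97             22.85
        16.0      10.40      11.98             15.18             -5.65
        24.0      11.93      12.00              0.60            -17.59
        32.0      12.00      12.00              0.00            -18.08
        40.0      12.00      12.00              0.00            -18.09
```

Reading: the sharper reconstruction (`b`) recovers far more of the true peak
in small lesions (+115% at 8 mm) and nothing extra once the sphere is large
against the PSF; normalizing by the cord (itself partial-volume-affected)
damps but does not remove the gain.  `report.mtv_summary`, `tlg_summary` and
`ce_summary` tabulate, per segmentation method, the median MTV on each
reconstruction, the median paired difference (absolute and in % of
reconstruction A), the paired-test p value, and the overlap statistics;
`report.transitions` carries the visual-score transition table.

A command-line interface mirrors the stages
(`petcompare simulate | quantify | segment | overlap | stats | run-all`);
phantom geometry is described in a small YAML file (see
`petcompare.config`), images and masks travel as NIfTI with a JSON sidecar
for the injection record.

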