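# Methods

## Scope and model

The package analyses *paired* PET images: two reconstructions of one
acquisition that differ in effective resolution and voxel grid.  All
quantities are defined on axis-aligned grids in world millimetres with
voxel-centre sampling and half-open voxel extents; volumes are reported in
cm³.  Oblique orientation matrices are rejected rather than silently
reinterpreted, and no operation resamples implicitly — cross-grid work goes
through an explicit nearest-neighbour (voxel-centre) mask resample.

### Uptake

SUV converts an activity concentration c (MBq/cm³) through the
decay-corrected injected dose: `SUV = c · w / (D · 2^(−Δt/T½))` with body
weight w in g, dose D in MBq, and Δt the injection-to-scan-start time in
seconds.  The decay reference time is scan start, not per-bed mid-time.  The
¹⁸F half-life defaults to 6586.2 s and can be overridden per record.  SUR
divides a lesion's SUV_max by the cord reference region's SUV_mean, measured
per reconstruction on that reconstruction's own image; SUR is therefore
invariant to any global multiplicative error, SUV is not (both facts are
tested).  The cord mask is supplied, never auto-segmented.

### Segmentation

All nine threshold rules reduce to an absolute SUV cut applied inside a
caller-supplied search region with a closed (≥) rule, so a percent-max mask
always contains its own peak voxel:

| method | cut (SUV units) |
|---|---|
| adaptive | `1.1693 · SUR_max^0.25 · cord_mean` (the `116.93 · SUR_max^−0.75` percent form) |
| SUV 2.5/3.5/4.5 | the parameter itself |
| SUR 2.5/3.5/4.5 | parameter · cord_mean |
| MAX40/50% | parameter/100 · SUV_max(search) |

Search-region confinement stands in for the clinical CT-based delineation;
unconfined static cuts at SUV 2.5 would leak into physiologic uptake.  No
connectivity constraint is applied by default (a largest-26-connected-
component mode exists behind a flag).  Empty masks — including an adaptive
percent above 100 — return MTV 0 with a `degenerate` flag; the pipeline
excludes such pairs from medians and counts them.  TLG (= MTV · SUV_mean,
identically the voxel-value sum times voxel volume) is attached only to the
SUV-based methods (static SUV, percent-max); SUR-cut volumes get none.

### Overlap

The classification error compares MTVs across reconstructions:
`CE = (FN + FP) / V_ref`, FN being reference-only volume and FP test-only
volume.  Both masks are resampled to the finer of the two grids before
counting — the coarser rasterization would destroy sub-voxel disagreement —
and the reference volume in the denominator is measured on that same
comparison grid, keeping the identity exact.  CE is 0 only for identical
rasterized masks, exactly 1 against an empty test mask, and satisfies
`CE(A,B)·V(A) = CE(B,A)·V(B)`.

### Agreement statistics

Tabulated relative differences use reconstruction A as the reference
(`100·(b−a)/a`); Bland–Altman differences use the pair mean, with limits of
agreement `bias ± 1.96·SD` (sample SD).  The ICC is the single-measure
two-way absolute-agreement coefficient from ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` with k = 2, and its 95% CI
is the standard F-based interval; pingouin's ICC(A,1) is used in the test
suite as an independent cross-check, never as the implementation.  The
Wilcoxon signed-rank test discards zero differences, mid-ranks ties, uses
the exact 2ⁿ sign-assignment null (computed by convolution over doubled
ranks) for n ≤ 25 and a tie-corrected normal approximation beyond; the
two-sided p is twice the smaller tail, capped at 1.  The choice between the
paired t test and Wilcoxon is configuration, not automated normality
testing.  Cohen's kappa follows the usual `(p_o − p_e)/(1 − p_e)` with an
optional 1–2 vs 3–4 dichotomization of the 4-point visual score; the
transition analysis reports row-conditional proportions (empty rows as
undefined, not zero) and counts crossings of the 2|3 boundary, the cut that
changes nodal staging.

## The phantom: what it emulates and what it does not

A high-resolution (1 mm isotropic by default) activity map holds spherical
lesions and a 5 mm-radius cord cylinder over a uniform background inside a
body ellipsoid filling 80% of the field of view (the ellipsoid only gives
the background finite support).  Rasterization everywhere is
centre-in-shape.  A reconstruction is emulated as isotropic Gaussian PSF
convolution (σ = FWHM/2.3548; edge-replication boundary, so a constant field
stays constant) followed by exact box-overlap mean downsampling to the
clinical grid — mass-preserving wherever the target grid covers the truth,
which the tests verify to 0.5% with sources ≥ 3 FWHM from the FOV edge.
Optional noise is multiplicative Gaussian (SD proportional to the local
value, negatives clamped), with per-reconstruction sub-streams spawned
deterministically from one integer seed; the default is noiseless, which the
analytic property checks assume.

This forward model captures the mechanism under study —
resolution-driven partial volume error — but not iterative OSEM
reconstruction, sinogram-space effects, scatter/attenuation, motion, lesion
heterogeneity or irregular shapes.  Consequences worth keeping in mind when
reading test results: uniform high-contrast spheres make relative-threshold
behaviour cleaner than clinical lesions, and for the *lowest* static cuts
(2.5) the sign of the MTV difference genuinely inverts once a sphere is
large against the PSF (the cut sits far below the blurred peak and tail
spreading dominates), so the static-vs-relative sign pattern is asserted
where the partial-volume effect is strong.

### Standard study conditions

Chosen once, on realism grounds, and used by all batteries: truth lesion
SUV 12 and background SUV 1 (clinical peak SUVs around 11 on the blurrier
protocol imply a truth contrast near 12:1), cord SUV 1.6 (clinical
SUV_max/SUR_max ratios imply a cord mean near 1.6), injection 178 MBq,
69 min uptake, 70 kg — the cohort-typical values.  Battery diameters are
8–40 mm; "small" lesions in sign-pattern summaries are the 8 and 12 mm
spheres, the diameter range implied by clinical nodal volumes
(0.4–1.3 cm³).  Lesion centres sit on voxel centres of the coarser grid so
peak sampling is aligned identically across diameters.  The noise level of
clinical images is not modelled and no attempt is made to match clinical
variance.

## Numerical choices

- Supra-threshold rule closed (≥); ties in Wilcoxon mid-ranked; zeros
  dropped.
- Grids compare equal within 1e−9 mm; images round-trip through NIfTI as
  float32 (≤ 1e−6 value error).
- The NIfTI affine's translation encodes the centre of voxel (0,0,0), i.e.
  origin + spacing/2 under this package's corner-origin convention.
- NN mask resampling has a surface-layer volume error of up to half the
  target spacing per face (tested against that bound and against a
  brute-force oracle); centre-in rasterization of a 10 mm sphere on a
  2 × 2 × 5 mm grid loses its polar caps (~0.14 cm³), so mask volumes on
  clinical grids are quantized — CE and MTV comparisons across grids
  therefore happen on the finer grid.
- Degenerate inputs fail loudly: empty reference masks, zero cord means,
  zero total variance in the ICC, all-zero Wilcoxon differences, double SUV
  conversion.

## Problem sizes

Batteries use single-lesion phantoms on a 120 × 120 × 100 mm FOV at 1 mm
(1.44 M voxels) and the six-lesion phantom a 240 × 160 × 100 mm FOV; the
full test suite runs in well under a minute and the acceptance script in a
few seconds on one CPU.  The ICC recovery simulation uses 100 replicates of
200 pairs (subject SD 2, noise SD 0.5, offset 0.5, closed-form ICC 0.9143).

## Known limitations

Only axis-aligned NIfTI volumes are supported; DICOM series and RT structure
sets are out of scope.  The visual-score cross-tabulation is consumed as
given (consensus reading between observers is not modelled), so the
inter-observer kappa of the source study is not reproducible from it — only
the reconstruction-to-reconstruction transition structure.  Clinical cohort
magnitudes (mean uptake gains, per-method median MTV differences in cm³)
depend on real lesion shape/heterogeneity distributions and are reproduced
in direction, not magnitude, by the sphere phantom.
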