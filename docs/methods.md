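# Methods

## Background and scope

Fluorescence visualization (FV) devices excite oral mucosa at ~425 nm;
healthy epithelium re-emits pale green autofluorescence while dysplastic
and malignant tissue absorbs the light and appears dark (fluorescence
visualization loss, FVL). The quantitative unit is the **G-value**: the
green-channel intensity (0–255) of an 8-bit RGB pixel. In a 4NQO-induced
rat tongue carcinogenesis model the stage sequence Control → low-grade
dysplasia (LGD) → high-grade dysplasia / carcinoma in situ (HGD/CIS) →
invasive cancer produces a characteristic G-value signature: a jump in
mean intensity at LGD, a decline with further progression, widening pixel
scatter, and a sign flip of the apex→root intensity gradient.

`fvquant` implements the analysis chain — image loading, measurement-line
profiling, stage statistics, inclination-line fits, ROC staging, group
tests — together with a synthetic image generator calibrated to the
published stage-level statistics, since no raw images from the study are
deposited. Everything downstream is therefore testable end to end with
known ground truth.

## Synthetic cohort model

One animal's field is

```
pixel(x, y) = m_a + s_a · (x − x_mid) + ε(x, y) − spot(x)
m_a ~ N(mean_g, between_sd²),  s_a ~ N(axial_slope, slope_sd²),
ε ~ N(0, within_sd²) i.i.d.
```

* The gradient is **centred on the measurement-line midpoint**, so `m_a`
  is the expected profile mean — the quantity the stage summary tables
  report. Anchoring at the apex would bias every group mean by
  `slope·(L−1)/2`.
* `within_sd` is the pixel-noise SD **about the axial trend**. The raw SD
  of a 200-px profile additionally contains the gradient's spread
  (`|slope|·sd(x) ≈ 1.7` G at slope 0.03), so the within-sample noise is
  estimated by `detrended_sample_sd` (residual SD about the fitted
  inclination line, N−2 denominator); `sample_sd` remains the plain N−1
  formula used for reporting per-profile variation.
* `slope_sd` realizes the within-stage mixture of positive and negative
  slopes seen in the stage summaries; a single deterministic slope per
  stage cannot produce it.
* Dark spots (FVL) are top-hat depressions of width `spot_width` and depth
  `spot_depth` at Poisson positions (`spot_rate` per 100 px of line);
  Gaussian-profile spots are available via `spot_profile="gaussian"`.
  The study reports only that irregular dark spots multiply with
  progression, so spot parameters are a package calibration, chosen once
  so that pooled pixel ranges widen monotonically from Control to Cancer
  (LGD 0.5/100 px, depth 8, width 2; HGD/CIS 1.5/12/3; Cancer 2.0/12/3).
* Fields are kept at full float precision; clipping to [0, 255] and 8-bit
  quantization happen at render time, so quantization error (variance
  1/12) can be separated in statistics tests.
* Pixels are independent apart from the shared gradient and spots. Real
  tongue images have anatomical spatial autocorrelation (papillae,
  keratin texture, the half-moon structure); this is deliberately not
  modelled. Consequently the synthetic between-animal profile
  concordance (mean pairwise Pearson r ≈ 0.0–0.3) is far below the ~0.85
  reported for real cohorts, where animals share anatomy. Tests passing
  on synthetic data therefore validate the estimators, not claims about
  real-tissue spatial structure.

Default stage presets (rat): means/between-SDs 32.5±3.2, 54.6±7.5,
46.1±6.2, 49.1±7.1; within-SDs 2.43/3.79/3.68/4.42; slopes +0.03 (SD
0.005), −0.03 (0.03), +0.002 (0.04), −0.03 (0.03); cohort sizes
10/11/15/14; 200-px lines. Human presets: four 50-px sites, means
37.4/40.6/44.1/36.2, within-SDs 1.34/4.72/3.74/10.59, no between layer.

Determinism: each animal's RNG stream is derived from
`SeedSequence([root_seed, crc32(stage), animal_index])`, so any animal is
reconstructible bit-exactly and cohorts are reproducible byte-for-byte
(truth JSON and images).

## Measurement

Profiles are sampled at `n_points` evenly spaced positions along the A→R
segment with **nearest-pixel lookup** (default): G-values are 8-bit
categories and interpolation would fabricate unobservable intensities;
bilinear sampling sits behind `interpolate=True`. The line is 1 px wide
by default (the protocol does not state a width); `band_width` averages
parallel offset lines. Masked pixels (e.g. the rat half-moon structure,
supplied as a companion mask image — automatic detection is out of
scope) become NaN and are excluded everywhere downstream.

## Statistics

* Group statistics **pool pixels** across a stage's profiles (the
  published group min/max clearly span pixel-level extremes); per-animal
  aggregation is available via `per_sample=True`.
* Pairwise profile concordance: profiles are resampled to the shortest
  length by evenly spaced index selection, Pearson r per unordered pair,
  mean over **all pairs** (the aggregation rule is unstated in the
  source; this is the documented choice). Per-pair p-values come from
  the standard t transform and are reported, not gated on.
* Histogram bins are right-open with default width 1 G-value (native
  quantization).

## Inclination line

Ordinary (vertical) least squares is the default reading of "the line at
minimum distance from all measured intensities": intensity is regressed
on a fixed pixel grid. Total least squares (orthogonal distances, via
the principal axis) is provided as `method="orthogonal"`; both coincide
on noiseless collinear data. Slopes with |a| < 1e−6 G/px are classed
"zero" and excluded from both the positive and negative class means.
Empty sign classes report mean/SD 0 for clean tabulation.

## ROC staging

Thresholds are placed at midpoints between adjacent distinct pooled
values (plus the minimum), so a reported cutoff separates the classes.
The scoring direction is chosen per comparison to make AUC ≥ 0.5 and is
recorded (LGD is *brighter* than Control, but HGD/CIS and Cancer are
*darker* than LGD). The positive class is the higher-grade side of each
comparison; sensitivity = TPR on that class at the Youden-index cutoff
(the published table does not state its cutoff rule, so empirical
cutoffs may differ from the printed ones by a few G-values). Ties in J
break toward the threshold nearest the midpoint of the class means;
indistinguishable classes carry a `degenerate` flag. The trapezoidal
AUC equals the tie-corrected Mann–Whitney U/(n₁n₂) to machine precision;
p-values use the tie-corrected normal approximation to U. The analysis
unit is pooled pixels per stage, consistent with the group statistics.
`gaussian_auc_oracle` provides the closed form Φ(Δμ/√(σ₁²+σ₂²)) for
simulated Gaussian classes; on the calibrated Control/LGD totals
(Δμ = 22.1, SDs 4.02/8.40) it gives 0.991, matching the published 0.99.

## Group tests

ANOVA and Dunnett-style many-to-one comparisons run on **per-animal mean
G-values** (pixels within an animal are pseudo-replicates), so n matches
the cohort sizes. Dunnett adjusted p-values are computed by seeded
Monte Carlo over the joint null of the comparison t statistics (group
means ~ N(0, 1/nᵢ), pooled variance ~ χ²(ν)/ν; default 10⁵ draws,
minimum 10⁴): simple, reproducible, and it reduces to the two-sample
t-test when only one comparison exists. The reference group is a
parameter (Control by default).

## Numerical choices and problem sizes

* Quantization at render adds variance 1/12 ≈ 0.083 G²; recovery tests
  account for it where it is resolvable.
* Acceptance-style recovery runs use the published cohort sizes for
  group means (50 animals × 200 px), 200 replicate profiles for SD
  recovery, 100 animals/class for pixel-level AUC, and 120 replicates
  for slope recovery — sizes at which every Monte-Carlo standard error
  is well below the quantity being recovered.
* Tolerances are 3 standard errors of the estimator concerned unless a
  fixed band is stated (slope ±0.01, AUC ±0.01).

## Known limitations

* No photorealistic anatomy, excitation physics, or keratin optics; the
  generator reproduces stage-level statistical structure only.
* Profile concordance on synthetic cohorts is structurally lower than in
  real cohorts (see above).
* Empirical Youden cutoffs are not expected to match published cutoffs
  exactly (unknown cutoff rule, synthetic scatter model).
* The human configuration has one profile per site, so group tests and
  concordance are undefined there; pixel-level ROC still applies.
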