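# Methods

## The measurement model

A developed assay spot is summarized by its *response*: 255 minus the
standard 0–255 luminance gray (`0.299 R + 0.587 G + 0.114 B`), so that a
darker (more developed) spot scores higher. Two gray conventions circulate
for such assays — one where 0 is white and one where 0 is black — so the
package computes both (`gray_standard`, `response`) and defines all
dose–response work on the response scale, where color development is a
positive, increasing signal.

The dose–response is logarithmic in concentration,

    y = a·ln(x) + b,    x in mM,

with defaults a = 36.958 response units per ln(mM) and b = 61.367 response
units (the response at exactly 1 mM). Although the curve is non-linear in
x, it is linear in ln(x), so calibration is ordinary least squares in
ln-space — no iterative fitting, and the recovered coefficients are exactly
the curve's printed parameterization. The model is clamped: a plain
`ResponseModel` clamps to the 8-bit range (0, 255), and
`ramp_clamped_model(scene)` clamps to the response interval the scene's
paper→stain color ramp can actually realize, which represents chromogen
saturation — a fully developed spot cannot get darker. The default
end-to-end scenario uses the ramp clamp, because its molar-range
concentrations (0.1–0.5 M) sit far beyond saturation of any physical brown
chromogen.

## The synthetic scene

`SceneParams` defaults (chosen once, as a plausible smartphone close-up of
a 4 mm test zone):

| parameter | default | meaning |
|---|---|---|
| image_size | 256×256 px | photograph crop |
| spot_center, spot_radius | (128,128), 80 px | spot geometry (ground truth) |
| paper_rgb | (0.96, 0.95, 0.92) | warm white filter paper |
| stain_rgb | (0.35, 0.24, 0.08) | fully developed iodine-brown product |
| illum_gradient | 0.08 | fractional left-right lighting drop |
| noise_sd | 4.0 response units | per-pixel sensor/film-grain noise |
| texture_sd | 0.015 reflectance | paper-fiber mottle amplitude |
| texture_scale | 4 px | Gaussian correlation length of the mottle |

Rendering order: (1) spot pixels linearly interpolate paper→stain and an
achromatic affine touch-up pins the disc-mean response to the model value
exactly; (2) the illumination ramp is centered on the spot so its disc mean
is 1; (3) the multiplicative texture field is renormalized to mean 1 over
the disc; (4) additive Gaussian response noise. Steps 2–3 therefore never
move the disc-mean response, and the pre-noise ROI mean equals the model
value to well within 0.5 response units at every attainable concentration.
All randomness flows from integer seeds through `numpy` generators;
identical parameters give bit-identical images, and dataset/stability
sub-seeds are fanned out deterministically from one global seed.

What the simulator does **not** emulate: camera optics and white balance,
JPEG compression (images are written as lossless PNG), perspective, coffee-
ring rims, multi-phone variability, and any non-monotone storage behavior.
Passing tests on this generator therefore demonstrate the correctness and
statistical behavior of the analysis code under controlled conditions, not
robustness to real-world photography artifacts.

## Segmentation

The spot is found chromatically: the background color is the modal coarse-
histogram color of a border frame (the spot is interior by construction in
this assay format), and each pixel's distance to it is measured after
subtracting the pixel's own mean brightness, which cancels achromatic
brightness shifts and makes the criterion a color difference rather than an
absolute threshold. Otsu's threshold, a morphological opening (disk radius
2) and the largest connected component give the spot; an equal-area disc is
fitted and eroded to `shrink_factor` (default 0.8) of its radius to exclude
rim effects. Degenerate inputs (chromatically uniform images, components
under `min_area` = 64 px) raise `NoSpotFound`.

## Features

45 moment features: mean, skewness (m₃/m₂^1.5) and non-excess kurtosis
(m₄/m₂², Gaussian = 3) of each of the 15 chromatic channels over the ROI
pixel multiset; a numerically constant sample (m₂ < 1e−12) reports skewness
0 and kurtosis 3. 6 texture/intensity features from the gray-level
co-occurrence matrix of `gray_standard`: Ng = 8 uniform bins of [0, 255],
single horizontal offset (0, 1), symmetric accumulation, pairs counted only
when both pixels are inside the ROI mask (the reason the GLCM is computed
in-package rather than with `skimage.feature.graycomatrix`, which has no
mask support; the two agree exactly on full-frame masks). Metric
conventions: entropy in bits with 0·log 0 = 0; correlation defined as 1
when a marginal spread vanishes; intensity is the mean of the unquantized
gray ROI.

The NTSC YIQ transform is pinned to the FCC coefficient matrix rounded to
four decimals — both chroma rows sum exactly to zero, so the attainable
extrema over the RGB cube are exactly ±0.5959 (I) and ±0.5229 (Q). HSV,
XYZ and CIELAB follow sRGB/D65 via `skimage.color`; achromatic hue is 0.

## Calibration and LOD

`fit_log_calibration` is OLS of response on ln(x) (≥3 distinct positive
concentrations); R² = 1 − SSres/SStot (0 for constant responses),
residual_sd = √(SSres/(n−2)). Inversion is `exp((y−b)/a)`, flagged
extrapolated outside the validated range, default (0.5, 14) mM — the range
over which the response is stable before saturation effects set in. The
limit of detection uses the signal-domain 3.3σ convention: y_LOD =
blank_mean + 3.3·blank_sd, inverted through the calibration. The log model
has no constant concentration-space slope, so the classical 3.3σ/slope
formula is deliberately applied in signal space before inversion; with a
3σ or different blank convention the LOD changes accordingly, which is why
the convention is exposed prominently rather than buried.

## Concentration prediction

The predictor is an epsilon-SVR on target log₁₀(x in mM), so one model
spans the physiological (0.5–20 mM) and high-intake (0.1–0.5 M) ranges.
Pipeline: `StandardScaler` → `SelectKBest` on a hardened univariate F
statistic → `SVR`. The filter matters: roughly two thirds of the 51
features are distribution-shape statistics whose between-image variation
under the default conditions is mostly per-image noise; standardization
inflates them to unit variance and an isotropic kernel then lets them
dominate the distance. Channels that track concentration correlate with
the log target near r = 1 while noise-dominated features show only chance
correlation (|r| ≲ 0.3 at these sample sizes), so the F filter separates
them sharply; the retained count k ∈ {12, 24, all} is a grid-search
hyperparameter, selected by cross-validation like C ∈ {0.1, 1, 10, 100},
epsilon ∈ {0.01, 0.1} and (RBF) gamma ∈ {0.5, 1, 2}/k. The F statistic is
hardened because numerically perfect correlations can make `f_regression`
return negative or non-finite scores through cancellation in 1−r², which
would rank a perfect predictor last; such scores are remapped to a large
finite value and constant-feature NaNs to 0.

Validation is replicate-grouped throughout: the 70/30 hold-out and the CV
folds split by replicate identifier, so correlated replicates never
straddle a split, and scaler/selector parameters are fitted on the
training split only. Reported R² is computed on the held-out split in
log₁₀ space. Predictions outside the training target range are flagged as
extrapolations. An auxiliary SVC (`train_range_classifier`) triages
samples into the mM vs M regime when a coarse decision is all that is
needed.

Under the default conditions (14 concentrations × 3 replicates, noise_sd
= 4) the held-out R² is ≈ 0.97 and a 7 mM unknown is recovered within a
few percent — comfortably inside the ±20% envelope the acceptance test
asserts across 20 noise realizations.

## Stability

`summarize_day` averages the ROI-mean response over a day's images;
`percent_intensity_change` is 100·(1 − last/first), positive for fading.
The simulator's decay is exponential in days, reaching (1 −
decay_fraction) at the final day (default 0.62 over 14 days, the default
storage condition being trehalose-stabilized reagents at 4 °C). Storage
condition labels are grouping metadata only; no between-condition test is
performed.

## Problem sizes and numerical choices

Tests and the acceptance checks run the full default 256×256 scene for the
end-to-end recovery (42 training images + 20 unknowns, ≈15 s) and reduced
96×96 scenes for CLI round-trips; the calibration-recovery check uses the
direct response-level simulation (27 observations), which is the exact
analogue of reading mean spot responses without rendering images.
Degenerate-input rules (constant samples, empty masks, unattainable
targets, zero-slope fits) all raise typed errors rather than returning
NaNs, and every tolerance used in the code (0.5 response units for the
simulator mean contract, 1e−12 variance floors) is stated at its
definition.

## Known limitations

- The synthetic spot interior is homogeneous up to texture and noise; real
  spots show radial development gradients and coffee-ring rims that the
  0.8-radius erosion only partially emulates.
- The GLCM uses a single offset; multi-offset averaging is out of scope.
- The LOD convention (3.3σ, signal-domain) is one of several in use and is
  a package choice, not a measured property.
- Calibration weighting is ordinary (unweighted) least squares; replicate
  heteroscedasticity is not modeled.
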