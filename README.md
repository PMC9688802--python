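# spotquant

Chemometric quantification of glucose from smartphone photographs of
paper-pad colorimetric assay spots.

Enzymatic paper sensors (µPADs) report an analyte as a developed color: a
glucose-oxidase / peroxidase / iodide cascade turns a paper test zone brown,
and the darkness of the spot in an ordinary smartphone photograph encodes
the glucose concentration. `spotquant` implements the full image-to-number
pipeline for such assays — and, because real assay photographs are rarely
shareable, ships a synthetic spot-image generator with complete ground
truth, so every stage can be validated end to end without any lab data.

The pipeline:

1. **Simulation** (`spotquant.synthetic`) — circular chromogenic spots on
   paper-textured background. The mean *response* of a spot (defined as
   `255 − gray`, gray being standard 0–255 luminance, so darker = larger)
   follows the logarithmic dose–response

   ```
   y = a·ln(x) + b,   a = 36.958, b = 61.367   (x in mM)
   ```

   clamped to the attainable range, with per-pixel Gaussian noise,
   paper-fiber mottle and an illumination gradient on top. Shelf-life decay
   over storage days is simulated by scaling the target response down
   monotonically.
2. **Preprocessing** (`spotquant.preprocessing`) — resize + median
   denoising, then chromatic segmentation of the spot (distance from the
   border paper color after removing per-pixel brightness, Otsu threshold,
   morphological opening) and erosion of the fitted disc to 80% radius to
   drop rim artifacts.
3. **Features** (`spotquant.colorspaces`, `spotquant.features`) — every ROI
   pixel is expanded into 15 chromatic channels (R, G, B, H, S, V, L\*,
   a\*, b\*, X, Y, Z, and NTSC Yn, I, Q with a pinned 4-decimal transform);
   mean, skewness and kurtosis per channel give 45 moment features, and a
   masked gray-level co-occurrence matrix adds contrast, correlation,
   energy, homogeneity, entropy plus the mean gray intensity — **51
   features** per image.
4. **Calibration** (`spotquant.calibration`) — least squares of response on
   ln(concentration), R², inversion `x = exp((y−b)/a)` with extrapolation
   flags, and a signal-domain 3.3σ limit of detection.
5. **Chemometrics** (`spotquant.chemometrics`) — an epsilon-SVR on
   standardized, univariate-filtered features predicting
   log₁₀(concentration), hyperparameters chosen by replicate-grouped
   cross-validated grid search.
6. **Stability** (`spotquant.stability`) — per-day mean response and the
   percent intensity change `100·(1 − last/first)`.

## Worked example

The `spotquant` command chains the stages through one YAML config and one
global seed (a 96×96 scene keeps this quick; defaults are 256×256):

```bash
spotquant simulate --config config.yaml --out run
#   wrote 42 images and manifest to run
spotquant extract  --manifest run/manifest.csv --config config.yaml --out features.csv
#   wrote 42 feature rows to features.csv
spotquant calibrate --features features.csv --config config.yaml --out fit.json
#   calibration: a=36.963, b=61.352, R^2=1.0000 -> fit.json
spotquant train    --features features.csv --config config.yaml \
                   --out-model model.joblib --out-report report.json
#   held-out R^2 = 0.9756; model -> model.joblib
spotquant predict  --model model.joblib --features features.csv --out pred.csv
spotquant simulate-stability --config config.yaml --out stab
spotquant stability --manifest stab/manifest.csv --config config.yaml --out series.csv
#   percent intensity change over 0..14 days: 61.87%
```

Reading the numbers: the 42 images cover 9 physiological concentrations
(0.5–20 mM) and 5 high-range ones (0.1–0.5 M), 3 replicates each. The
calibration refit recovers the generating coefficients (a = 36.963 vs
36.958, b = 61.352 vs 61.367) because the ROI mean response averages the
pixel noise away; `r_squared ≈ 1` and `residual_sd ≈ 0.31` response units
quantify the fit. The SVR's held-out R² (0.9756, computed on a replicate
group never seen in training) measures predicted-vs-actual agreement in
log₁₀ space across both assay ranges. The stability run simulates a 62%
reagent-activity loss over 14 days and measures 61.87% back from the
images.

The feature schema (channel order and the 51 column names) is part of the
public interface: `spotquant.FEATURE_NAMES`, channel-major
(`R_mean, R_skew, R_kurt, …, Q_kurt`, then `glcm_contrast,
glcm_correlation, glcm_energy, glcm_homogeneity, glcm_entropy,
gray_intensity`).

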