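# Methods

`lemnaquant` quantifies growth of floating aquatic plants (duckweed,
*Lemna gibba*) from tube-rack photographs and turns the resulting growth
curves into a salinity-tolerance estimate per clone. This note documents
the models, the tunable parameters, the synthetic data generator, and the
numerical choices, in enough detail to judge what a passing test suite
does and does not demonstrate.

## Image quantification

### Top view: plant surface area

Plants are segmented by color, not shape. The RGB photo is converted to
CIELAB (D65 illuminant) and reduced to the a* (green–magenta) channel,
mapped to 8-bit as `a* + 128` clipped to [0, 255]; chlorophyll-green
pixels land well below mid-gray (~40–90), neutral backgrounds at ~128.
A fixed threshold (default **120**, `segmentation.threshold`) marks dark
pixels as plant; connected components smaller than `segmentation.min_size`
(default **50 px**, 8-connectivity) are removed as noise. Both defaults are
calibration values — they suit the synthetic fixtures and must be re-tuned
for a real rig, where the threshold choice dominates quantification error.

Each photo holds three tubes. Three circular regions of interest (config:
first center, spacing, radius) partition the image; a connected component
is assigned to the ROI containing its **centroid** and contributes its full
pixel count there, so every component counts in exactly one tube. Components
whose centroid falls in no ROI are discarded. An alternative — assigning a
component to every ROI it overlaps — would double-count straddling
components; the centroid rule was chosen to keep per-tube areas additive.

### Side view: mat depth

Depth uses a row-threshold rule on the segmented mask of the tube's column
slot: a pixel row counts toward the depth if its white-pixel count reaches
`depth.row_threshold` (default: half the slot width). Rows need not be
contiguous; sparse rows from reflections simply fail the threshold. The
default ties the measurement to cultures dense enough to span the tube.

### Side view: barcode identity

Tube labels are Code128. Because exposure and label rotation vary, decoding
retries over a grid: rotations (outer loop, default {0, ±3, ±6, ±9, ±12}°,
0° first, nearest-neighbor resampling to keep bar edges crisp) ×
binarization thresholds (inner loop, default {60, 80, …, 220}); the first
successful decode wins and its parameters are reported. The decoder itself
is a pure-numpy scanline decoder: it run-length-encodes several horizontal
lines of the binarized crop, quantizes 6-run groups to the 11-module symbol
widths, and validates start symbol, checksum and stop pattern. Quantization
is per symbol, so slowly varying module width (perspective, mild skew) is
tolerated; in practice a single scanline survives rotations up to roughly
`atan(height/width)` of the label, and the rotation retry covers the rest.

## Growth curves

Top-view records carry no identity, so they are linked to barcodes via a
fixed camera pairing (each top camera has a dedicated side partner imaging
the same positions; default 1↔2, 3↔4), same tube position, and nearest
timestamp within `pairing.tolerance_minutes` (default 10 min). Records
whose side barcode never decoded are dropped with a warning — a missing
identity cannot be repaired downstream. Curves are keyed by barcode,
sorted by time, with elapsed time in fractional days from each curve's
first observation; duplicate passes (< 1 min apart) keep the later record.

## Relative growth rate

RGR is the slope of ln(area) against time (day⁻¹), the standard
exponential-phase growth measure. Because cultures lag after transplanting
and plateau at tube capacity, a single whole-curve fit would understate the
rate; instead every window of `rgr.window_days` (default **10 days**,
closed interval, anchored at each observation, ≥ 3 points) gets its own
ordinary-least-squares fit, and the **maximum** slope with adjusted
R² ≥ `rgr.min_fit` (default **0.8**) is the sample's RGR. Ties break to the
earliest window. Windows containing a zero-area point are skipped (ln
undefined). Adjusted R² is `1 − (1−R²)(n−1)/(n−2)`; when the residual
variance of ln(area) is below the double-precision noise floor the fit is
treated as exact (R² = 1), so constant series yield slope 0 with a clean
fit rather than numerical garbage.

Before any fitting, a viability filter drops samples that never grew: a
sample passes only if some run of consecutive observations, each with area
≥ `filter.min_area_px` (default **1000 px**), spans at least
`filter.min_days` (default **15 days**). With imaging five days a week,
"15 consecutive days" is read as a calendar span of a consecutive-
observation run; a config flag (`filter.count_observations`) switches to
counting 15 consecutive observations instead.

Selecting the maximum windowed slope is upward-biased under measurement
noise (order statistics of correlated OLS slopes); the bias shrinks with
the noise and is below ~0.01 day⁻¹ at the generator's default σ = 0.05.

## Dose–response and EC50

Per-sample RGRs are pooled across replicates and fitted per clone with the
five-parameter log-logistic family

    f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))^f

(lower/upper asymptotes c, d; slope b; inflection e; asymmetry f). Dose 0
is handled by the analytic limit (d for b > 0), never by offsetting doses.
Before fitting, the lowest dose at which **no** sample in the trial was
viable gets RGR 0 substituted for every designed replicate, and all
strictly higher doses are removed — a uniformly lethal concentration
carries real information (zero growth), while higher doses add none.
Lethality is judged trial-wide by default (`per_clone` switches it).

Fitting is bounded nonlinear least squares (SciPy trust-region-reflective)
on (b, c, d, ln e, ln f), initialized at c₀ = min response, d₀ = max
response, e₀ = geometric mean of positive doses, b₀ = f₀ = 1, with a
multi-start over b₀ ∈ {1, 0.5, 2}. Fitting ln e and ln f enforces
positivity without constraint kinks.

EC50 is the dose at which the fitted curve equals **half the 0 mM growth
rate**. The baseline is the observed mean RGR at dose 0 by default
(`dose_response.baseline_mode = "observed"`); `"fitted"` uses the upper
asymptote d instead. The crossing is found by Brent's method on
(0, 2·max dose] at 10⁻⁶ relative tolerance, flagged extrapolated when it
exceeds the tested range, and absent when the curve never crosses.

Uncertainty comes from a case-resampling bootstrap (default **500**
iterations): within every dose, replicates are resampled with replacement
to their original count; the model is refit, the baseline recomputed from
the resample, and EC50 re-solved. Failed refits or non-crossing resamples
are dropped (not imputed); the SD of the surviving EC50s is reported with
the effective count, and flagged unreliable if more than half failed.
Replicates are sorted within dose before resampling so the result is
invariant to input order; per-clone random streams derive deterministically
from one master seed.

## Synthetic data generator

The generator emulates the salinity trial: 6 clones × 6 added-sodium doses
(0, 50, 100, 200, 300, 400 mM) × 6 replicates = 216 cultures, imaged
Monday–Friday for four weeks (20 imaging days over a 25-day span).

Per sample, true area follows exponential growth after a transplant lag,
capped at a carrying capacity, with lognormal multiplicative measurement
noise:

    area(t) = min(A₀·exp(r·max(0, t − lag)), K) · exp(N(0, σ²))

Defaults: A₀ = 600 px, lag = 1 day, K = 30 000 px, σ = 0.05. True rates
follow a log-logistic decline in dose, r(x) = d/(1 + (x/e)^2.5), with
per-clone (d, e); the most tolerant clone is parameterized to grow at
0.19 day⁻¹ at 100 mM — 70% of its optimal rate — and doses ≥ 200 mM are
lethal for every clone (areas decay at 0.4 day⁻¹), mirroring the trial
this package is built to analyze. Measured areas are rounded to whole
pixels by default; `quantize_px=False` disables rounding so noiseless
simulations are analytically exact.

Image rendering draws hard-edged scenes: green elliptical colonies
(RGB ≈ (60, 140, 60) with per-tube jitter) inside dark tube openings on a
neutral background, sub-noise-size glare speckles, a full-width green mat
band of the specified row depth, and Code128 labels at configurable
rotation and contrast. Ground-truth areas are counted from the painted
pixel mask, so the manifest is exact by construction. The renderer does
**not** emulate anti-aliased edges, condensation, focus blur, uneven
illumination, tube curvature or refraction — passing pipeline tests on
these fixtures demonstrates the algorithms are correct, not that the
default calibration transfers to a physical rig.

## Problem sizes

The test suite and the acceptance script run the full 216-culture trial at
the curve level (cheap) and image-rendered trials at reduced size (one to
two clones, two to four doses, two to three replicates), which keeps a full
run of everything in a few minutes on one CPU while still exercising every
pipeline stage end to end.

## Known limitations

* Color-threshold segmentation; no learned segmentation (deliberately).
* The top↔side linking rule (camera pairing + position + time proximity)
  is a reconstruction of an unstated rig convention; it is config-exposed
  and is the first thing to re-examine on real data.
* EC50 comparisons between clones come with bootstrap SDs but no formal
  hypothesis test.
* The Code128 decoder targets clean printed labels; it is not a general
  barcode reader (no EAN/QR, no blur deconvolution).
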