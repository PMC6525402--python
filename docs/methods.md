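# Methods

This note documents the models, conventions and design choices behind
`pcotex`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, and where
the genuinely open choices were settled.

## Problem setting

Posterior capsule opacification is graded from retroillumination
photographs in which opacities appear as texture against the bright pupil.
The grader operates on a circular region of interest (ROI) — clinically the
central 4.0 mm of the IOL optic — and must cope with saturated Purkinje
reflexes from the axial illumination, which destroy the texture under them.

## Images, ROI and reflex exclusion

* Images are unit-scaled grayscale rasters (`GrayImage`), read from 8/16-bit
  PNG/TIFF; RGB input is reduced with configurable luminance weights
  (default Rec. 601: 0.299, 0.587, 0.114).
* The ROI is a parameterized centered circle given in pixels (optionally
  derived from a millimetre diameter and a pixel pitch). Membership is the
  **open disc**: a pixel belongs iff its center lies strictly inside;
  boundary ties are excluded. This makes the rule determinate and exactly
  testable, and the mask exactly symmetric under quarter turns.
* Reflex pixels are those with intensity ≥ a saturation threshold (default
  0.98), dilated by a square structuring element (default radius 2).
  Excluded pixels contribute to neither the classification output nor the
  numerator/denominator of the global score — saturated pixels carry no
  texture information, so treating them as "lost data" and renormalizing
  over the remainder is the only defensible choice.

## Texture features

All features are computed per pixel over a `window_size` × `window_size`
neighbourhood (default 17, odd), with reflect padding so every ROI pixel
receives a full feature vector. Defaults were fixed once, before any
experiment, at conventional values; all are configurable (`FeatureConfig`).

**Windowed GLCM (5 planes).** The image is quantized to `glcm_levels`
(default 16) bins by `floor(I·levels)` clamped at the top. One
co-occurrence matrix per window accumulates, for *every* window pixel as
anchor and *both* signed directions of each displacement (default
distance-1 at 0°, 45°, 90°, 135°), the pair (anchor level, partner level),
the partner being read from the padded image. Energy, entropy (bits),
contrast, homogeneity, and correlation follow the standard definitions with
0·log 0 ≡ 0 and correlation ≡ 0 for zero-variance windows. Anchored
counting with both signs was chosen because it makes the GLCM planes
*exactly* equivariant under 90° image rotation (the signed 8-offset set is
closed under quarter turns, and the per-window counts are integers), a
property the rotated-repeat experiment depends on.

**First-order statistics (5 planes).** Window mean, standard deviation,
skewness, excess kurtosis (all via raw moments of globally mean-centered
intensities, which avoids catastrophic cancellation), and the entropy of
the `glcm_levels`-bin window histogram. Zero-variance windows (variance
≤ 1e−12) define skewness and kurtosis as 0.

**Gabor responses (24 planes by default).** DC-corrected complex Gabor
kernels for 3 frequencies (0.08, 0.16, 0.32 cycles/px, spanning the cell
and blob scales of the textures; all below Nyquist) × 4 orientations.
Kernels for orientations ≥ 90° are *exact array rotations* of the
(θ − 90°) kernel, so the default bank is exactly closed under quarter
turns. The response magnitude is summarized by its window mean and window
standard deviation.

**Local fractal dimension (1 plane).** Differential box counting: for box
size *s*, the window is tiled by *s*×*s* cells and each cell contributes
`floor(max·M/s) − floor(min·M/s) + 1` intensity boxes (M = window size).
Because a corner-anchored tiling is not symmetric under rotation when
`M mod s ≠ 0`, counts are summed over the four corner-anchored tilings —
integer counts, hence bit-exact quarter-turn equivariance. The dimension is
the least-squares slope of log N(s) against log(1/s) over the default box
sizes {2, 3, 5, 9}, clamped to the surface range [2, 3]. A constant image
evaluates to ≈ 1.96 before clamping (flat surface), full-range white noise
to ≈ 2.7.

The default stack is 5 + 5 + 24 + 1 = 35 named planes, in that fixed order.

## Classifier and feature selection

A diagonal-covariance Gaussian Bayes classifier (per-class sample means and
variances, variance floor 1e−6 on z-scored features, uniform priors by
default, empirical priors optional) assigns each pixel the class maximizing
log prior + summed log densities; ties resolve to the lowest class index.
Diagonal covariance was preferred over full covariance for robustness with
small training samples; full covariance is deliberately out of scope.

Features are z-scored with training-set statistics (scale floored at 1e−8).
The subset is chosen by SFFS — forward inclusion of the candidate that most
improves stratified k-fold (default 3) accuracy, with conditional
exclusions whenever removing a feature beats the best known subset of the
smaller size — capped at `max_features` (default 10), deterministic given
the seed, ties toward the lower feature index. The reported trace is the
best criterion value seen up to each accepted forward step and is therefore
non-decreasing.

**Rotation equivariance of the trained model.** Under a 90° image rotation
the Gabor planes are not invariant but *permute* across the orientation
quartet (θ ↔ θ ± 90°). The grader therefore (a) selects Gabor features in
orientation quartets (one SFFS candidate per frequency × statistic) and
(b) ties normalization and per-class Gaussian parameters across each
selected quartet using pooled statistics. Together with the exactly
equivariant GLCM/fractal/histogram planes this makes the pixel classifier
invariant to quarter-turn rotation up to float-level noise (~1e−13 in the
log scores), which in practice never flips an argmax: rotated repeat
images grade *identically*. Float-order effects in the windowed moments and
Gabor convolutions are the only asymmetry left.

Training pixels are sampled stratified per class (default 300/class,
seeded) from class *interiors*: regions eroded by half the window size, so
no training window mixes textures. The trained model is serialized as
versioned JSON (selected feature names, per-class parameters, priors,
normalization, feature configuration, provenance metadata).

## Scoring

The global score is the exact weighted mean of class weights over scored
pixels (masked and reflex pixels excluded from both sums), i.e. a convex
combination of the weights: raw ∈ [0, 4]. Default weights (0, 0.8, 1, 2,
3, 4) are configurable but must be non-negative and non-decreasing in class
order. The 0–100 reporting conversion is linear (× 100 / max weight = × 25
by default); the conversion is a package choice — only the endpoints of the
reporting scale are externally fixed. The qualitative output colors classes
black / cyan / blue / green / yellow / red, masked pixels mid-gray; the
legend is bijective, so rendered maps are losslessly decodable.

## Agreement statistics

Validity: sample Pearson correlation (via `scipy.stats.pearsonr`) between
graded scores and reference severities; undefined for zero-variance input.
Repeatability: for paired differences *d*, the mean difference, CI
halfwidth z·sd(d)/√n and coefficient of repeatability CR = z·sd(d), with
the sample sd (n−1) and z = 1.96 at the 0.95 level. The normal quantile
(rather than Student-t) is the convention of clinical repeatability
reporting; note that a printed CI halfwidth of 1.2 with CR 5.1 at n = 20 is
consistent with these formulas (1.2·√20 ≈ 5.4) within print rounding. A
t-quantile variant is available via `use_t=True`. CR/halfwidth = √n holds
exactly by construction.

## Synthetic data: what it emulates, and what it does not

The generator renders 160×160 scenes (ROI diameter 85% of the short side by
default) — large enough for ~60 17-px windows across the ROI while keeping
a full experiment inexpensive. The ROI is partitioned into ~24 blob-shaped
regions (argmax of smoothed Gaussian fields); classes are assigned to
regions by a severity-matched draw followed by greedy single-region
repairs until the realized weighted-mean score is within 0.08 raw units
(2 scaled points) of the request; severities 0 and 100 are exact by
construction. The recorded `truth_severity` is always the exact rescaled
score of the realized truth map.

Texture recipes are phenomenological, parameterized by the visual
attributes that drive the features: clear = smooth bright field (sd
< 0.05); honeycomb A/B = jittered-grid cell tessellations (spacing 15 vs
8 px, border depth 0.12 vs 0.26); plate = smooth sheet with darkened
directional streaks; pearl plate = mid-density overlapping blobs; Elschnig
pearls = dense high-contrast blobs. Reflexes are saturated discs (radius
3–6 px). Repeat pairs are either exact `rot90` rotations or re-renders of
the identical truth map with a fresh photon-noise draw (sd 0.01), ≤ 2 px
translation and ±5% gain — emulating consecutive exposures with slight
fixation and illumination changes.

Per-scene seeds derive from a master seed through
`SeedSequence([master, *indices])`, reduced below 2³¹ (`child_seed`), so
manifests are reproducible and train/test sets with different master seeds
are disjoint by construction.

**Limitations.** The generator does not emulate IOL edges, anterior-capsule
remnants, optical vignetting, or the photometric response of the
acquisition chain; region boundaries are hard (real PCO transitions are
gradual); large single pearls defined by their contour rather than their
texture are out of scope (as is any contour-based detector). Passing the
synthetic experiments therefore demonstrates the *mechanics* of the
pipeline — feature correctness, selection determinism, score exactness,
rotation-exact repeatability — not clinical-grade accuracy on real
photographs, which would require training on labelled clinical data
through the same interfaces.

## Numerical conventions collected

* 0·log 0 ≡ 0 in all entropies; entropies in bits.
* Variance thresholds: window statistics treat variance ≤ 1e−12 as zero;
  classifier variances floored at 1e−6 (z-space); normalization scales
  floored at 1e−8.
* Ties: argmax ties toward the lowest class index; SFFS ties toward the
  lowest feature (group) index.
* Strict (open-disc) ROI membership; boundary pixels excluded.
* Box sums via integral images — exact for the integer-valued counts that
  feed GLCM, histogram and fractal features.
* Fractal dimension clamped to [2, 3]; slope fitted over ≥ 3 box sizes.

## Experiment sizes used in the test suite

Training: 12 scenes, severities evenly spanning 0–100, 300 px/class.
Held-out accuracy: 6 scenes, interior pixels (half-window erosion).
Validity: 60 scenes, disjoint master seed. Repeatability: 10 rotated +
10 consecutive pairs (the consecutive scenes include 2 reflexes each).
These sizes keep a full run to a few minutes while leaving every check far
from its threshold in practice (accuracy ≈ 0.98 vs the 0.90 bound;
validity r ≈ 0.99 vs 0.9; CR ≈ 3 vs 10).
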