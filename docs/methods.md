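# Methods

`hscurve` classifies pigmented skin lesions (PSLs) captured with a
snapshot hyperspectral dermoscopy camera — 50 × 50 pixel cubes with 125
bands across 450–950 nm — into *melanoma*, *other malignant* and *benign*
classes. The method does not model skin optics; it exploits the
relationship between local brightness and local texture contrast across
the spectrum.

## The model

**Calibration and normalization.** Raw sensor counts RI are flat-fielded
against a white-tile reference WI and a closed-shutter dark reference DI,

    CI = (RI − DI) / (WI − DI),

and the result is clipped to [0, 1] (noise can push counts below the dark
level; specular glints above the 99 %-reflective tile). The cube is then
min–max normalized to [0, 1] *globally* (one min and max per cube, not per
band): the curve features below compare magnitudes across bands, which a
per-band rescale would destroy. The normalization scope is a design choice
of this package; a per-pixel-spectrum variant would remove the very
illumination differences the global rescale is meant to absorb while also
erasing the albedo differences the classifier uses.

**ROI curves.** A 7 × 7 window at a fixed spatial position yields, for
each band k, a point (x_k, y_k) = (window mean, window sample standard
deviation, denominator N − 1). The 125 points in band order form an *ROI
curve* in the mean/std plane. Window centers are swept over the inclusive
grid (16, 16)…(35, 35) in the instrument's 1-based pixel convention
(0-based 15…34 internally), giving 20 × 20 = 400 candidate curves whose
footprints jointly cover the central 26 × 26 = 676 pixels. The stride is
fixed at 1.

**Pruning.** Curves are ordered by x before fitting. A complexity
statistic — total variation of x along band order divided by the x-range;
1 for monotone curves — triggers thinning of convoluted curves: the
x-range is split into 50 equal bins and each nonempty bin contributes
(mean x, median y). The median acts as a 1-D grayscale-morphology erosion
of spikes. Threshold 3.0 and bin count 50 are configurable; for simple
curves only exact-duplicate x values are collapsed (median y). Output x is
strictly increasing and never longer than the input.

**Weighted robust quartic fit.** Each pruned curve is fitted with
f(x, b) = b0 x⁴ + b1 x³ + b2 x² + b3 x + b4 by minimizing
Σ w_i (y_i − f(x_i, b))², with fixed observation weights from the
heteroscedasticity model w(y) = 1/(0.011 + 0.011 y)² evaluated at the
*observed* y_i (low-std points are trusted more; evaluating at the fitted
response instead is available as an option but makes the objective
non-quadratic). On top of the fixed weights, bisquare IRLS (tuning 4.685,
scale = MAD/0.6745 of the √w-scaled residuals) down-weights outliers.
Convergence is declared when the maximum absolute coefficient change (in
original-x coefficients) falls below 1e−8, capped at 100 iterations;
non-convergence returns the last iterate flagged `converged=False`.
Abscissae are centered and scaled internally; the z-space solution is
mapped back through an exact linear coefficient transform. Degenerate
inputs: fewer than 5 distinct x values is an identifiability error; an
all-constant y returns the constant polynomial exactly.

**Features.** With f the fitted quartic and x_1…x_n the curve's own
abscissae (not a dense grid — keeps the features anchored to observed
data; a grid option exists):

| feature   | definition                                  | role              |
|-----------|---------------------------------------------|-------------------|
| df_mean   | mean f′(x_i)                                | slope of std vs mean |
| ddf_mean  | mean f″(x_i)                                | curvature         |
| df_at_max | f′ at the x_i maximizing f                  | terminal steepness |
| totm      | a·df_mean + b·ddf_mean + df_at_max          | melanoma score    |
| mean      | mean f(x_i)                                 | std level         |
| mabdf     | mean + mean \|f′(x_i)\|                     | benign score      |
| prod      | max x_i · max f(x_i)                        | malignant score   |

with a = 1, b = 0.1. The inclusion of df_at_max in totm follows the
fuller textual definition of the score; a `totm_variant="figure"` switch
drops it. The count of f″ sign changes inside the x-range (0, 1 or 2) is
computed and reported but not used by the default rule, since no threshold
for it was ever trained.

**Classification.** Per cube, the extrema of the features over all 400
candidate curves (max totm, max mean, max prod, min mean, min mabdf) feed
a two-step cascade with trained constants c = 2.86, d = 0.05, e = 0.395,
f = 0.109, g = 0.05:

1. melanoma iff max totm > c;
2. else malignant iff max mean > d or max prod > e;
   else benign iff min mean < g or min mabdf < f;
   else the mean-above/below-g boundary decides.

All inequalities are strict; equality falls through. Because the extrema
come from different windows, the malignant and benign conditions are not
mutually exclusive: malignant is tested first — for a screening tool a
false positive is the cheaper error. No per-class window selection happens
at inference; all 400 candidates contribute to all extrema, which is the
only label-free reading of the procedure. Evaluation counts
{melanoma, malignant} as positive and additionally scores melanoma-vs-rest.

## The phantom generator

The clinical cubes behind the trained thresholds are not public, so the
package ships a generator of labelled phantoms. The classifier consumes
only ROI-curve statistics, so phantoms control exactly those: a *class
profile* is a pair of per-band vectors (μ_k, σ_k) drawn from class-typical
ranges —

* benign: σ flat in ≈[0.018, 0.034] over μ rising ≈0.10 → 0.34;
* malignant: σ ≈ 0.08–0.29 rising moderately over μ ≈ 0.09–0.38;
* melanoma: σ convex-increasing (quadratic in μ, amplitude ≈0.3) over
  μ ≈ 0.05–0.31, giving steep terminal slope and high curvature.

Every draw is verified at construction: the noiseless (μ, σ) curve is
fitted and the decisive feature must clear its threshold by a margin
(0.5 on totm, 0.02 on mean/mabdf — sized to absorb sampling noise and
clipping bias); off-class thresholds must stay untriggered. Failing draws
are resampled (≤ 20 attempts).

A cube realizes its profile through a 7-periodic two-level texture tile
(values ≈ −0.788 on 30 cells and ≈ +1.244 on 19 cells; exactly zero mean
and unit sample std) emulating a bimodal pigment network. Because the tile
period equals the window side, *every* aligned 7 × 7 lesion window
contains each tile value exactly once and reproduces (μ_k, σ_k) exactly in
the noiseless limit. The two levels are bounded so μ + σ·t stays in
[0, 1] for all class profiles — a symmetric (Gaussian) texture would clip
at 0 on high-σ melanoma bands and systematically flatten the realized
curves. Per-voxel Gaussian measurement noise (default sd 0.01) is added on
top, and the lesion disk is sized to cover the whole sweep footprint. A
3 × 3 glare patch (reflectance 1) and shadow patch (0) sit in background
corners outside the footprint, pinning the cube's global range so the
min–max normalization is the identity on phantoms. The raw cube is emitted
through the inverse calibration raw = CI·(WI − DI) + DI with a smooth
synthetic white field and near-constant dark field, so the calibration
stage is exercised end to end.

What the phantoms do *not* emulate: real lesion-boundary windows that mix
tissue types, spatially varying (non-periodic) texture, wavelength-
dependent focus, chromophore absorption structure, or convoluted
(non-monotone-in-x) curves beyond what noise induces. Passing phantom
tests therefore validates the pipeline's mechanics and decision logic
under the stated curve-shape model, not clinical performance.

## Numerical choices and benchmark sizes

* Sample std uses ddof = 1 throughout (configurable).
* The non-robust fit is checked against a closed-form weighted
  normal-equations solve (agreement ≲ 1e−9 on random 125-point curves).
* The parameter-recovery benchmark runs on equispaced abscissae over the
  standardized interval [−1, 1], where the quartic monomial basis is well
  conditioned (coefficient-SE floor ≈ 0.017 at noise sd 0.01, n = 125;
  on [0, 1] the same floor is ≈ 0.48, so coefficient-space recovery is not
  a meaningful target there). Measured median coefficient L2 error at
  sd 0.01 is ≈ 0.014.
* Dataset-level validation uses a balanced 30-cube phantom set (10 per
  class) at the default noise level; a full run takes well under two
  minutes on one core.
* Ties in the per-cube extrema break toward the lowest (row, col) window
  center, making summaries order-independent.

## Known limitations

* Thresholds are the published trained constants; no retraining facility
  is provided (the training data are private).
* The pruning filter's form (equal-width binning, per-bin median) and its
  complexity trigger are this package's concrete choices for an operation
  that was described only loosely; both are configurable.
* MSE values reported by the fit are unweighted means of squared
  residuals, with the weighted objective exposed separately; no claim is
  made about matching any externally reported MSE scale.
* ENVI support covers float32/float64 BSQ/BIL/BIP with in-header
  wavelength lists — enough for interchange, not a full ENVI
  implementation.
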