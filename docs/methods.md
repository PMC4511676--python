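# Methods

This note records the models implemented in `salbias`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
benchmark does and does not demonstrate.

## The spatial prior and its tests

Salient-object centroids are taken as the mean of foreground pixel
centers under the convention that pixel (row i, col j) of an M×N image
maps to ((j+0.5)/N, (i+0.5)/M); this makes centroids of symmetric masks
exact and puts images of any resolution on the unit square, y-axis down.

The prior states that, about the pole (0.5, 0.5), centroid angles are
uniform on [−π, π] and radii half-Gaussian.  Two practical notes:

- *Folding.*  A point (r, θ) with θ < 0 can be rewritten as (−r, θ + π),
  giving angles in [0, π] and signed radii in (−∞, ∞).  Under the prior
  the signed radii are then symmetric-Gaussian with mode 0, so the radial
  hypothesis can be tested either as radii-vs-half-normal or as folded
  radii-vs-normal.  Both are computed; on model data their PPCCs agree to
  about 2·10⁻³ at n = 1000 (they are different statistics of the same
  sample, so exact equality is not expected).
- *Truncation.*  Objects touching the border pull their mask centroid
  inward.  Border-truncated masks are deliberately **not** excluded (an
  exclusion flag exists for sensitivity analysis): the model is one-sided
  half-Gaussian rather than border-truncated, accepting a small tail
  distortion in exchange for standard tests.

**PPCC.**  The probability-plot correlation coefficient is the Pearson
correlation between order statistics and model quantiles at plotting
positions p_i = (i − 0.5)/n (Filliben order-statistic medians are a
config option; the difference is negligible for n in the hundreds).  It
is location-scale invariant, so no distribution parameters need fitting.
The fit hypothesis is rejected when the PPCC falls below a critical
value.  Two critical-value sources ship with the package:

- `printed`: literature values at the benchmark setting n = 1000,
  α = 0.05 — 0.8880 (uniform family) and 0.9984 (normal/half-normal
  family).  The uniform entry is far below the actual null 5th
  percentile at that n (≈ 0.9991), i.e. it is a very conservative bound;
  the normal-family entry matches its null percentile closely.
- `monte_carlo` (default at untabulated settings): null 5th/1st
  percentiles estimated from 50,000 seeded replicates per (model, n) for
  n ∈ {10, …, 2000}, interpolated linearly in log n and clamped outside
  the grid.  Only these calibrated values make the test an approximately
  size-α test, which is what the calibration tests check.

The companion hypothesis of *no correlation* is tested by
t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom (two-sided).

## Center-bias models

The pixel map is the separable product of two 1-D Gaussian densities
centered on the image, evaluated at pixel offsets from ((N−1)/2, (M−1)/2).
Defaults σ_x = sqrt(0.0223)·N and σ_y = sqrt(0.0214)·M tie the prior's
spread to the measured per-axis centroid variance in normalized units;
both are parameters everywhere they appear.  Maps are peak-normalized to
1 by default so that product/min/max fusion with an already-normalized
bottom-up map cannot rescale it arbitrarily.  The per-segment score is
the same Gaussian evaluated at the region centroid in normalized units.

## Region contrast, debiasing, fusion

- Segmentation uses Felzenszwalb's graph-based method (scale 200,
  σ = 0.8, min size 50 — recorded in each run's config; deterministic for
  fixed parameters).  The backend is pluggable: any label map can be
  supplied in place of the built-in segmentation.
- Color histograms: each sRGB channel quantized to 12 levels
  (bin-center representatives converted to Lab), then the most frequent
  colors covering ≥ 95% of the pixels are kept and the remainder merged
  into their nearest kept color in Lab.  Both knobs are configurable.
- The spatial weight is exp(−D_s/σ_s²) on Euclidean centroid distances in
  normalized coordinates, *distance not squared*, exactly as the model
  family prints it; a squared-distance switch exists because upstream
  formulations differ.  σ_s² defaults to 0.4, the value conventional in
  the region-contrast family.
- The contrast sum runs over all other regions (no spatial-connectivity
  pruning).
- Debiasing row-normalizes the weights over the other regions; rows then
  sum to 1 exactly (machine precision), which is verified as an
  acceptance property.  A subtlety worth recording: the raw model's
  implicit bias is *not* detectable by rigidly translating every
  centroid — the weights depend only on pairwise distances, which are
  translation invariant.  The bias manifests when scene content shifts
  relative to frame-fixed context (background regions), which is how the
  tests operationalize it.
- Region scores are min-max normalized before center-bias fusion; fused
  per-region scores are painted onto the pixel lattice and min-max
  normalized again for export.  Because every evaluation measure sweeps
  thresholds over the map's own value range, min-max rescaling never
  changes a metric; fusion outputs are therefore kept raw internally and
  rescaled only for writing PNGs.
- Four fusion schemes: convex w_C·S_C + (1−w_C)·S_B, Hadamard product,
  min, max, with an option to weight the min/max inputs.  The default
  center-bias weight is w_C = 0.25 — inside the regime where the convex
  fusion helps on center-biased data while staying conservative; w_C is
  swept (0 to 1 in 0.025 steps by default) by `sweep_wc`/`salbias sweep`.

## MSSS

Per pixel (i, j) the surround is the largest centered symmetric window
[i−y₀, i+y₀]×[j−x₀, j+x₀] with y₀ = min(i, M−1−i), x₀ = min(j, N−1−j).
Saliency is the Euclidean Lab distance between the surround's mean color
(computed with a summed-area table; verified against naive averaging)
and the pixel's Lab value smoothed with a 5×5 binomial kernel,
border-replicated.  The construction is 90°-rotation equivariant, which
is tested.  This is an independent implementation of the
symmetric-surround idea, not a bit-exact port of any particular binary.

## Evaluation protocol

- Thresholds: 256 levels spanning the map's value range inclusive
  (an exact-enumeration mode over distinct values is used by the oracle
  tests); pixels with value ≥ t are positives.
- Aggregation: per-image mean precision/recall/FPR at each threshold
  (default), or pixel-pooled counts; both are first-class because
  published protocols are ambiguous on this point, and they genuinely
  differ on heterogeneous sets.
- Precision at the empty-prediction point is defined as 1; F_β is 0 when
  precision and recall are both 0.
- PR AUC integrates the interpolated-precision envelope
  p̃(r) = max{precision_i : recall_i ≥ r} over recall (trapezoid mode
  selectable); ROC AUC is the trapezoid over (FPR, TPR) with (0,0) and
  (1,1) appended — a constant map scores 0.5 by this convention, and a
  perfectly inverted map scores 0 (reported as computed).
- Hit-rate uses the optimistic tie rule: any globally maximal pixel
  inside the object counts; full-map ties are flagged.
- Significance: per-image metric vectors of two variants are compared
  with two-sample t-tests — two-tailed for equal means and one-tailed
  for "the variant is worse" — at α = 0.05.  Per-image populations are
  an assumption; resampled-run populations would also be defensible.

## Synthetic scenes: what they emulate

Each scene is one clearly colored object (ellipse or rectangle,
5–20% of the image area, ΔE ≥ 40 to the background) rendered at a
centroid drawn from the prior (σ_r = 0.211, chosen so the per-axis
centroid variance σ_r²/2 matches the measured 0.0223; verified by Monte
Carlo), with Gaussian pixel noise (σ = 0.01 in sRGB units).  Centroids
are clipped to the unit square and objects may be truncated by the
borders, reproducing the inward-shifted tail of real border-touching
objects.  Two structural features matter for the center-bias experiments
and were chosen on realism grounds:

- the background consists of two color bands (ΔE ≈ 15 apart, random
  horizontal/vertical split), because real backgrounds segment into
  several off-center regions; a single full-frame background region
  would place its centroid exactly at the image center and invert the
  meaning of a centroid-level prior;
- three distractor blobs (1–4% area, ΔE ≥ 30) are placed uniformly but
  outside a 0.3 central exclusion radius: the scene's premise is a
  single centrally composed subject, so competing clutter is peripheral.
  A `no-bias` preset instead draws object centroids uniformly over
  [0.1, 0.9]², emulating surveillance/robotics imagery.

Default scene size is 120×160 pixels; the end-to-end direction-of-effect
experiment uses 200 scenes.  These sizes keep a full pipeline run in the
tens of seconds while leaving segmentation non-trivial.

What passing these tests shows: the statistical machinery is calibrated,
the implementations match their defining equations, and on data that
*satisfy the prior's assumptions* the explicit center bias improves
debiased region contrast while the prior alone underperforms any real
contrast model.  What it does not show: performance on natural
photographs — synthetic scenes have no texture, no lighting gradients,
single unambiguous objects, and their color statistics are far simpler
than web images, so absolute metric values here are not comparable to
published benchmark numbers.

## Degenerate inputs and numerical conventions

Empty masks are rejected (centroid) or skipped with a warning
(evaluation).  Constant maps normalize to all-zeros with a warning; a
flat image yields an all-zero MSSS map (dynamic range below 10⁻⁹ in Lab
units is treated as flat).  Single-region segmentations score zero
contrast with a warning, and debiased weights are undefined (signaled)
for K = 1.  A zero-radius polar point takes angle 0.  PPCC requires
n ≥ 3 and a non-constant sample; |r| = 1 returns the p → 0 limit of the
correlation t-test.  All randomness flows through seeded NumPy
generators; dataset generation spawns per-scene child seeds from a
`SeedSequence`, so datasets are reproducible scene-by-scene.

## Known limitations

- The half-Gaussian radial model ignores border truncation by design;
  for generators with much larger σ_r the clipping distortion would
  become visible to the fit tests.
- Monte-Carlo critical values carry sampling error of about ±0.0002 at
  the 5th percentile; for n far outside the tabulated grid the clamped
  values are conservative.
- The region-contrast pipeline assumes sRGB inputs and the D65 Lab
  transform; no other color spaces are provided.
- Min/max fusion of very differently distributed maps is sensitive to
  the peak normalization of the center-bias map; the weighted-extrema
  option mitigates but does not remove this.
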