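# salbias

Center-bias-aware salient object detection and the statistics behind it.

Photographs taken by people are composed: the object of interest tends to
sit near the image center.  `salbias` is a toolkit for studying and
exploiting that *photographer's center bias* in salient object detection.
It is aimed at researchers in computational visual attention who want to

- **test the spatial prior** — are salient-object centroids really
  distributed with uniform polar angle and half-Gaussian radius about the
  image center?  (`salbias.ppcc`, `salbias.lattice`)
- **use the prior** — fuse an explicit Gaussian center-bias map with
  bottom-up saliency, or remove the *implicit* bias hidden inside
  region-contrast saliency (`salbias.center_bias`, `salbias.region_saliency`,
  `salbias.pixel_saliency`, `salbias.fusion`)
- **measure the effect** — threshold-sweep benchmark evaluation with
  significance testing (`salbias.evaluation`), on real data or on synthetic
  scenes whose centroid statistics follow the prior (`salbias.synthetic`).

## The models

**Spatial prior.**  Object centroids, in normalized coordinates
(x, y) ∈ [0, 1]², are represented in a polar frame about the pole
(0.5, 0.5): angle θ ~ Uniform[−π, π], radius r ~ |N(0, σ_r)|.  Goodness of
fit is tested with the probability-plot correlation coefficient (PPCC):
the Pearson correlation between the sorted sample and the model quantiles
at plotting positions (i − ½)/n, compared against tabulated critical
values; a companion t-test checks the hypothesis of no correlation.

**Center-bias map.**  S_C(x, y) = g(μ_x − x, μ_y − y; σ_x, σ_y), a separable
product of two 1-D Gaussian densities centered on the image; the default
σ fractions derive from the measured centroid spread (variance ≈ 0.022 per
axis in normalized units).

**Region contrast (RC / LDRC).**  With regions r_k from graph-based
segmentation, Lab color histograms f(c_k;i) and sizes w(r_i):

    S(r_k) = Σ_{r_i ≠ r_k}  Ŵ(r_k, r_i) · w(r_i) · D_r(r_k, r_i),
    D_r(r_1, r_2) = Σ_i Σ_j f(c_1;i) f(c_2;j) ‖Lab_i − Lab_j‖,
    Ŵ(r_k, r_i) = exp(−D_s(r_k, r_i)/σ_s²).

The raw weights Ŵ implicitly favor central regions (their weight sums are
larger).  The *locally debiased* variant (LDRC) row-normalizes them,
Ŵ̌(r_k, r_i) = Ŵ(r_k, r_i) / Σ_{r_i ≠ r_k} Ŵ(r_k, r_i), so each row sums
to exactly 1.  An explicit center bias g(C(r_k)) of each region centroid
can then be fused back in (RC+CB, LDRC+CB).

**MSSS.**  Pixel-based maximum-symmetric-surround saliency: the Lab
distance between each (smoothed) pixel and the mean color of the largest
image-contained window centered on it.

**Fusion.**  S_P = f(S_C, S_B) with f one of convex (w_C S_C + (1−w_C) S_B),
Hadamard product, min, max (the extrema optionally weighted).

**Evaluation.**  Sweeping a binarization threshold over each map yields
maximum F1 and F_β (β = 0.3), PR AUC (interpolated-precision envelope),
ROC AUC and hit-rate; per-image-averaged or pixel-pooled aggregation, and
two-sample t-tests between algorithm variants.

## Worked example

```python
import numpy as np
from salbias import (SceneSpec, make_dataset, analyze_centroids,
                     RegionContrast, evaluate_dataset)

# 100 synthetic scenes with center-biased object placement
images, masks, manifest = make_dataset(100, SceneSpec(), seed=7)

# 1. does the spatial prior hold on the generated masks?
report = analyze_centroids(masks)
print(np.round(report.mean, 4))                      # [0.493  0.4853]
print(round(report.angle_test.ppcc, 4))              # 0.997   (no rejection)
print(round(report.radius_test.ppcc, 4))             # 0.9874  (no rejection)

# 2. does the explicit prior improve debiased region contrast?
for name, est in [("LDRC", RegionContrast(debias=True)),
                  ("LDRC+CB", RegionContrast(debias=True,
                                             center_bias="convex", wc=0.25))]:
    s = evaluate_dataset(est.fit().transform(images), masks)
    print(name, round(s.f1, 4), round(s.roc_auc, 4), round(s.hit_rate, 2))
# LDRC    0.8107 0.9779 0.64
# LDRC+CB 0.8553 0.9871 0.77
```

The centroid statistics reproduce the prior (PPCC near 1, neither fit
hypothesis rejected), and convex fusion of the Gaussian prior at weight
w_C = 0.25 lifts every measure — max-F1 from 0.81 to 0.86, hit-rate from
0.64 to 0.77 — while the standalone prior alone is far weaker than either.

The same pipelines are scriptable from the shell:

```bash
salbias synth --n 100 --out data/ --seed 7
salbias saliency data/scene_*.png --method ldrc+cb --wc 0.25 --out maps/
salbias analyze data/*_mask.png --out report/
salbias evaluate --maps maps/ --masks data/ --out eval/
salbias sweep --images data/ --masks data/ --method ldrc+cb --out sweep/
```

Estimators follow scikit-learn conventions (`get_params`/`set_params`,
`fit`/`transform`), so they compose with sklearn meta-utilities.

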