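# siftstab

Keypoint-stability analysis and threshold tuning for SIFT-based registration
of 2D tomographic slices (e.g. cone-beam CT).

## The problem

Feature-based registration of medical slices with SIFT is usually run with
the detector's default selection thresholds — a contrast threshold of 0.04
on the interpolated DoG response `|D(x̂)|` and an edge-response threshold of
10 on the ratio `λmax/λmin` of the principal curvatures of `D` at the
keypoint. Those defaults were not chosen for tomographic data. `siftstab`
provides a principled way to tune them: it measures each keypoint's
**stability** — the fraction of random similarity transforms `Tᵢ` under
which the keypoint is re-detected within 5 px (checked at octave level) —
and correlates stability with the keypoint's own contrast and eigenvalue
ratio. A positive contrast correlation and a negative eigenvalue-ratio
correlation mean stricter thresholds preferentially keep the stable
keypoints, allowing registration of equal quality from far fewer features.

The package contains:

* a from-scratch SIFT implementation (`siftstab.sift`) with both thresholds
  as first-class parameters and both the 26-neighbor L∞ and 6-neighbor L1
  extremum rules;
* a transform lab (`siftstab.transforms`): twelve families of random
  similarity transforms (4 DOF, about the image centre) with image/point
  warping;
* the stability analysis (`siftstab.stability`) and a normality-gated
  statistics layer (`siftstab.stats`: Shapiro–Wilk/KS, Pearson/Spearman,
  mean±SD vs median/IQR);
* a registration benchmark (`siftstab.register`): mutual-nearest-neighbor
  (cross-check) descriptor matching, RANSAC-wrapped closed-form 4-DOF
  similarity estimation, and difference-image RMSE scoring over the valid
  overlap;
* a threshold-sweep pipeline (`siftstab.sweep`) and a synthetic CBCT-like
  phantom generator (`siftstab.phantom`), so everything runs without access
  to clinical data;
* a CLI (`siftstab phantom|detect|stability|register|sweep`).

## Worked example

```python
import siftstab as st
from siftstab import stability, sweep

# build a study: 27 synthetic slices, one shared set of 12 random transforms
cfg = st.SweepConfig(n_images=27, n_transforms=12, image_size=256, seed=0)
study = sweep.build_study(cfg)

records = []
for i, img in enumerate(study.images):
    records.extend(stability.compute_stability(img, study.transform_sets[i]))

rep_contrast, rep_evr = stability.stability_vs_property(records)
print(len(records), rep_contrast.method)
print(f"contrast: rho={rep_contrast.rho:+.3f} p={rep_contrast.p_value:.2e}")
print(f"evr:      rho={rep_evr.rho:+.3f} p={rep_evr.p_value:.2e}")
```

prints (seed 0):

```
499 spearman
contrast: rho=+0.182 p=4.44e-05
evr:      rho=-0.192 p=1.58e-05
```

Read: across 499 reference keypoints, stability rises with keypoint
contrast and falls with the eigenvalue ratio, both significant at
α = 0.05 — keypoints barely above the contrast threshold, or close to the
edge-response limit, are the ones that disappear under transformation.
Raising the contrast threshold and lowering the eigenvalue-ratio threshold
therefore discards preferentially unstable keypoints.

Registering a slice against a transformed copy:

```python
T = st.AffineTransform2D.from_params(5, -3, 10, 1.1, center=(127.5, 127.5))
res = st.register_pair(study.images[0], st.warp_image(study.images[0], T),
                       T_true=T)
print(res.status, round(res.good_match_rate, 2), round(res.rmse, 4))
print([round(v, 2) for v in res.estimated.params_about((127.5, 127.5))])
```

```
ok 1.0 0.0096
[4.81, -2.85, 9.99, 1.1]
```

i.e. the planted transform (tx=5 px, ty=−3 px, 10°, scale 1.1) is recovered
to within a fifth of a pixel and a hundredth of a degree, every
cross-checked match is consistent with the ground truth, and the residual
difference image has RMSE ≈ 0.01 on the [0, 1] intensity scale.

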