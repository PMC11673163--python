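# Methods

`siftstab` studies how the two keypoint-selection thresholds inside the SIFT
detector — the contrast threshold and the Hessian eigenvalue-ratio (edge)
threshold — govern the *stability* of keypoints under geometric
transformation, and what that implies for feature-based registration of 2D
tomographic slices. This note records the models, conventions, parameter
choices and limitations behind the implementation.

## Detector

The detector is a from-scratch implementation of Lowe's pipeline.

**Scale space.** The image (float, [0, 1]) is embedded in a Gaussian pyramid
of `O` octaves with `s + 3` levels per octave. Within an octave, adjacent
levels differ by the factor `k = 2^(1/s)`; the absolute scale of level `i` in
octave `o` is `σ(o, i) = σ₀ · 2^o · k^i`. Defaults are Lowe's standard
values: `σ₀ = 1.6`, `s = 3`, assumed input blur 0.5 px, and
`O = floor(log₂ min(H, W)) − 3` when unset. No initial 2× upsampling is done
by default (configurable): the octave-level bookkeeping used by the stability
analysis is simpler without a −1 octave, and the phantoms have no fine
detail below the base sampling rate. Downsampling takes every second pixel
of the level whose smoothing is `2σ₀`.

**DoG and extrema.** Difference-of-Gaussians levels are adjacent-level
subtractions, `D[i] = G[i+1] − G[i]` (`s + 2` per octave). Candidates are
strict local extrema of the DoG cube on interior levels, at least 5 px from
the raster edge (at octave resolution). Two neighborhood definitions are
implemented: the classical 26-neighbor L∞ rule (full 3×3×3 cube minus the
centre, the default) and the 6-neighbor L1 rule (`2(n+1)` axial neighbors
with `n = 2`), which accepts a superset of the L∞ extrema. Ties are broken
by rejection (strict inequalities), so plateaus yield no duplicate
candidates.

**Refinement and the two thresholds.** Each candidate is refined by up to 5
iterations of the second-order Taylor fit (3D gradient/Hessian of the DoG
cube, offset = −H⁻¹g; an exactly singular Hessian, as on an ideal ridge,
falls back to the minimal-norm pseudo-inverse step so the candidate still
reaches the filters). A candidate whose offset never settles below 0.5 is
rejected as *diverged*. The interpolated value `|D(x̂)|` is the keypoint's
**contrast** and is compared with the contrast threshold directly on the
[0, 1] intensity scale (default 0.04). Note that several public
implementations first divide the threshold by `s`; this one does not, which
makes the configured threshold exactly the quantity stored on the keypoint.
The **eigenvalue ratio** is computed from the 2×2 spatial Hessian of `D`:
the candidate is rejected as *edge-like* if the Hessian is indefinite
(det ≤ 0), if its trace has the same sign as the extremum value, or if
`λmax/λmin` exceeds the threshold (default 10). The actual ratio — not the
`tr²/det` proxy — is stored on every keypoint so it can be correlated with
stability downstream.

**Orientation and descriptor.** Orientation uses the standard 36-bin
gradient histogram (magnitude-weighted, Gaussian window of width 1.5× the
octave-level scale, radius 3× that width), one smoothing pass of the
[1, 4, 6, 4, 1]/16 circular kernel, peaks ≥ 80% of the maximum, and
parabolic peak interpolation; each peak spawns an oriented copy. The
descriptor is the classical 4×4×8 array of gradient histograms sampled in a
window rotated by the keypoint orientation, with trilinear bin
interpolation, L2 normalization, clamping at 0.2, and renormalization. Flat
patches yield the all-zero descriptor. Samples falling outside the raster
are simply skipped; a keypoint is dropped only when no valid sample remains.

Keypoint count is non-increasing in the contrast threshold and
non-decreasing in the eigenvalue-ratio threshold, and a stricter run's
keypoints are a subset of a looser run's — the pipeline's candidate
enumeration and refinement are identical across threshold settings (the
raw-|D| prefilter at half the contrast threshold preserves this, because
interpolation can at most roughly double a surviving candidate's contrast).

## Transform lab

Benchmark transforms are similarities (4 DOF: tx, ty px; angle, degrees;
uniform scale) drawn uniformly and continuously from twelve parameter
families covering translation-only (±10 px), small (1–5°) and large
(30–45°) rotations, up- (1.1–1.5) and down-scaling (0.7–0.9), and their
combinations. The single most consequential convention: rotation and
scaling act **about the image centre**, not the origin — a 30–45° rotation
about the corner would expel most content from the frame and make warped
images incomparable to their references. One fixed set of twelve transforms
(one draw per family) is shared by all images of a study. Images are warped
by inverse mapping with bilinear interpolation and zero fill; point sets are
mapped exactly. Coordinates are 0-based pixel centres, ordered (x = col,
y = row).

## Stability

A reference keypoint is *re-detected* under transform `T` when some keypoint
of the warped image lies within 5 px of `T(reference)`, with the residual
measured on the octave grid of the **test** keypoint (divided by
`2^octave_test`): checking at octave level avoids the error of mapping
octave-level detections back to base resolution, and using the test side
avoids re-deriving which octave the reference keypoint should land in under
scaling. Octave indices are deliberately not required to match — scaling
transforms legitimately move keypoints across octaves. Assignment is
one-to-one, greedy by ascending distance, so no test keypoint is consumed
twice. The stability rate is occurrences divided by the number of
transforms (e.g. 6 of 12 → 0.5).

Stability detection runs **without orientation assignment**: stability is a
purely geometric property, and orientation assignment duplicates keypoints
at multi-peak locations, which would inject correlated duplicate records
into the correlation analysis and distort one-to-one matching.

Stability is then correlated against each keypoint's stored contrast and
eigenvalue ratio through the statistics layer below.

## Statistical protocol

Normality is tested with Shapiro–Wilk for `n < 5000` and with a
Kolmogorov–Smirnov test against a normal with sample-estimated mean/SD for
larger samples (a Lilliefors-style usage whose reported p-value is the
standard KS p, conservative under estimated parameters; `n = 5000` exactly
takes the KS branch). Normal samples are described as mean ± SD and
correlated with Pearson's r; anything else uses median/IQR (linearly
interpolated quartiles) and Spearman's ρ. Pearson is used only when *both*
variables pass normality. All tests are two-sided at α = 0.05; p-values are
reported in full. No multiple-testing correction is applied. Constant
samples are flagged degenerate (not normal); zero-variance inputs produce a
not-computable correlation report rather than an exception.

## Registration benchmark

Descriptor matching is mutual-nearest-neighbor under Euclidean distance
(cross-check; k = 1 in both directions), with equal-distance ties resolved
to the lowest index. Lowe's ratio test is implemented nowhere in the
default path — cross-checking replaces it. The 4-DOF similarity is solved in
closed form on demeaned coordinates (`a = Σp·q/Σ|p|²`, `b = Σp×q/Σ|p|²`,
scale = √(a²+b²), θ = atan2(b, a)) and wrapped in RANSAC (2-point minimal
samples, 3 px inlier tolerance, 1000 iterations, fixed seed, final refit on
the consensus set), because even cross-checked matches contain occasional
outliers; a plain least-squares mode is available by flag. Registration
quality is the RMSE of the difference image between the warped reference
and the test image over the **valid-overlap mask** (output pixels whose
pull-back lies inside the source raster), so border zero-fill does not
contaminate the score; a full-frame mode exists for sensitivity analysis.
The good-match rate (benchmark mode, ground truth known) counts pairs whose
test keypoint lies within 5 px of the mapped reference keypoint — the same
tolerance as the stability rule, the only tolerance in evidence for this
purpose. Runs with fewer than 10 keypoints on either image, or failed
estimations, are returned as flagged failure records and excluded from
sweep medians.

## Sweep

The sweep varies one threshold at a time with the other at its default
(contrast grid 0.02–0.14 in steps of 0.02; eigenvalue-ratio grid 3–12),
registers every (reference, warped) pair per grid point, and aggregates the
median good-match rate, the RMSE distribution, and the mean keypoint count
normalized to the default-threshold count (so the fraction is exactly 1 at
(0.04, 10)). The per-axis optimum is the argmin of median RMSE, ties broken
toward the stricter threshold; a combined run re-evaluates the optima
jointly, since per-axis medians do not establish a cumulative effect.

## Phantom generator

Clinical CBCT slice collections are rarely shareable, so all experiments run
on synthetic slices designed to reproduce the three intensity populations of a
cone-beam CT slice: a dark air background (0.02), a mid-intensity
soft-tissue body (an ellipse at 0.32 with smoothed-noise texture of
amplitude 0.08 and configurable correlation length, default 24 px), and
high-contrast bone-like primitives — ellipses with a bright Gaussian-ridge
cortical rim (amplitude 0.45–0.65, width 4–10% of the elliptical radius)
over a mid-level trabecular core (0.10–0.25). Additive Gaussian noise
(SD 0.02 by default) is clipped to [0, 1]. Rims exercise the edge-response
filter, cores and texture the contrast filter. Everything is a pure
function of the spec (size, structure count, noise SD, texture scale, seed),
so phantoms are bit-reproducible; datasets derive per-image seeds from a
base seed and re-draw any candidate whose normalized cross-correlation with
an accepted image reaches 0.95.

What the phantoms do **not** emulate: beam hardening, ring and streak
artifacts, scanner-dependent noise spectra, and — importantly — the heavy
upper tail of bone/air edge contrast in clinical data. Phantom keypoint
contrasts rarely exceed ~0.1, so at the strictest contrast settings
(≥ 0.08) detections can vanish entirely, whereas clinical slices with sharp
bone/air interfaces retain far more. Sweep conclusions at the top of the
contrast grid therefore say little about clinical data; the correlation
*signs* and the registration machinery are the transferable results.

## Problem sizes and study defaults

The default study is 27 slices of 256×256 px with 6 structures each, and
the twelve-family transform set; that yields roughly 500 reference
keypoints, enough power to resolve rank correlations of magnitude ~0.1 at
α = 0.05 (a 10-image study was visibly underpowered for effects of that
size). The registration sweep in the reproduction script runs at a reduced
scale (3 images × 3 transforms, thresholds near the defaults), which is
sufficient for median trends on phantoms. Measured on fixed seeds, the
phantom study recovers a positive stability–contrast correlation and a
negative stability–eigenvalue-ratio correlation, both significant.

## Numerical choices and degenerate inputs

* Strict inequalities in extremum detection; plateau ties are rejected.
* Refinement: ≤ 5 iterations; exactly singular 3D Hessians use a
  pseudo-inverse (rcond 1e-6) minimal-norm step; offsets ≥ 0.5 move the
  candidate and re-fit; leaving the valid interior → diverged.
* Keypoints deduplicated after refinement on (octave, level, position
  rounded to 0.1 px).
* Descriptor windows are clipped to the raster; a keypoint is dropped only
  if no sample survives. Degenerate flat patches keep an all-zero
  descriptor (matching is still defined; such rows match arbitrarily and
  are filtered by RANSAC).
* Intensity renormalization of an input image leaves keypoint positions
  bit-identical (detection depends on the [0, 1] image only).
* 16-bit PNG is the fixture format; quantization error (≈ 1.5e-5) is
  negligible against all tolerances used.

## Known limitations

* The phantom contrast distribution is narrower than clinical CBCT (above);
  absolute sweep optima on phantoms need not transfer to clinical data.
* The KS normality branch uses estimated parameters with the standard KS
  p-value (anti-conservative for rejecting normality is not a concern here;
  it is conservative, and at the n > 5000 sizes involved the test is
  decisive anyway).
* RANSAC with 2-point samples assumes the similarity model is correct; it
  will happily fit a similarity to data generated by a more general
  deformation.
* Runtime scales linearly in image count and transform count and roughly
  in pixels; the descriptor stage dominates at default settings.
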