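"""SIFT detector: scale space, DoG, extrema, refinement, orientation,
descriptors, full-pipeline invariants."""

import numpy as np
import pytest

import siftstab as st
from siftstab import imgio, sift


class TestScaleSpace:
    @pytest.mark.parametrize("s,k", [(1, 2.0), (3, 2.0 ** (1 / 3))])
    def test_level_scale_factor(self, s, k):
        cfg = st.SiftConfig(n_intervals=s)
        assert cfg.k == pytest.approx(k, abs=1e-9)

    def test_octave_rasters_halve(self):
        img = np.random.default_rng(0).uniform(size=(512, 512))
        ss = st.build_scale_space(img, st.SiftConfig(n_octaves=4))
        sizes = [o.shape[1] for o in ss.octaves]
        assert sizes == [512, 256, 128, 64]
        assert all(o.shape[0] == 3 + 3 for o in ss.octaves)

    def test_sigma_strictly_increases_within_octave(self):
        cfg = st.SiftConfig()
        img = np.random.default_rng(1).uniform(size=(128, 128))
        ss = st.build_scale_space(img, cfg)
        for o in range(ss.n_octaves):
            sig = [ss.sigma(o, i) for i in range(cfg.n_intervals + 3)]
            assert all(b > a for a, b in zip(sig, sig[1:]))
        assert ss.sigma(1, 0) == pytest.approx(2 * ss.sigma(0, 0))

    def test_too_small_image_for_octaves_errors(self):
        img = np.zeros((64, 64))
        with pytest.raises(ValueError, match="octaves"):
            st.build_scale_space(img, st.SiftConfig(n_octaves=6))


class TestDoG:
    def test_constant_image_gives_zero_dog(self):
        dog = st.build_dog(st.build_scale_space(np.full((96, 96), 0.5)))
        for o in dog.octaves:
            assert np.max(np.abs(o)) < 1e-12

    def test_level_counts(self):
        cfg = st.SiftConfig(n_intervals=3, n_octaves=2)
        dog = st.build_dog(st.build_scale_space(np.zeros((128, 128)), cfg))
        assert all(o.shape[0] == 3 + 2 for o in dog.octaves)

    def test_impulse_dog_matches_analytic_kernel_difference(self):
        """For a unit impulse the DoG at the impulse equals the difference of
        the two effective Gaussian kernels' central values, 1/(2 pi sigma^2)."""
        cfg = st.SiftConfig(n_octaves=1)
        img = np.zeros((129, 129))
        img[64, 64] = 1.0
        dog = st.build_dog(st.build_scale_space(img, cfg))
        for i in range(2):  # first two DoG levels, before truncation matters
            s_lo = np.sqrt((cfg.sigma0 * cfg.k ** i) ** 2 - cfg.assumed_blur ** 2)
            s_hi = np.sqrt((cfg.sigma0 * cfg.k ** (i + 1)) ** 2 - cfg.assumed_blur ** 2)
            expected = 1 / (2 * np.pi * s_hi ** 2) - 1 / (2 * np.pi * s_lo ** 2)
            assert dog.octaves[0][i, 64, 64] == pytest.approx(expected, rel=0.02)


def brute_force_extrema(dog, neighborhood, border):
    """Independent exhaustive scan over every interior sample."""
    offsets = sift.NEIGHBOR_OFFSETS[neighborhood]
    found = []
    for o, d in enumerate(dog.octaves):
        L, H, W = d.shape
        for l in range(1, L - 1):
            for y in range(border, H - border):
                for x in range(border, W - border):
                    c = d[l, y, x]
                    gt = all(c > d[l + dl, y + dy, x + dx] for dl, dy, dx in offsets)
                    lt = all(c < d[l + dl, y + dy, x + dx] for dl, dy, dx in offsets)
                    if gt or lt:
                        found.append((o, l, y, x))
    return found


class TestExtrema:
    def test_neighborhood_sizes(self):
        assert len(sift.NEIGHBOR_OFFSETS["linf"]) == 26
        assert len(sift.NEIGHBOR_OFFSETS["l1"]) == 6

    def test_constant_stack_has_no_extrema(self):
        dog = st.build_dog(st.build_scale_space(np.full((96, 96), 0.3)))
        assert st.detect_extrema(dog) == []

    @pytest.mark.parametrize("neighborhood", ["linf", "l1"])
    def test_injected_extremum_found_exactly(self, neighborhood):
        cfg = st.SiftConfig(n_octaves=1, neighborhood=neighborhood)
        dog = st.build_dog(st.build_scale_space(np.zeros((64, 64)), cfg))
        dog.octaves[0][2, 20, 31] = 1.0  # interior level, interior pixel
        got = st.detect_extrema(dog, neighborhood)
        assert got == [(0, 2, 20, 31)]
        assert got == brute_force_extrema(dog, neighborhood, cfg.border)

    def test_matches_brute_force_on_random_stack(self):
        rng = np.random.default_rng(7)
        cfg = st.SiftConfig(n_octaves=1)
        dog = st.build_dog(st.build_scale_space(rng.uniform(size=(48, 48)), cfg))
        for nb in ("linf", "l1"):
            got = sorted(st.detect_extrema(dog, nb))
            assert got == sorted(brute_force_extrema(dog, nb, cfg.border))

    def test_l1_extrema_superset_of_linf(self):
        rng = np.random.default_rng(8)
        dog = st.build_dog(st.build_scale_space(rng.uniform(size=(64, 64)),
                                                st.SiftConfig(n_octaves=1)))
        linf = set(st.detect_extrema(dog, "linf"))
        l1 = set(st.detect_extrema(dog, "l1"))
        assert linf <= l1  # fewer constraints in L1 comparison


def quadratic_dog(x0=0.3, y0=-0.2, l0=0.1, peak=0.08,
                  ax=0.004, ay=0.006, al=0.003, shape=(5, 21, 21),
                  center=(2, 10, 10)):
    """DoG cube with a known quadratic maximum at the sub-pixel offset
    (x0, y0, l0) from ``center``; the analytic extremum value is ``peak``."""
    L, H, W = shape
    cl, cy, cx = center
    l, y, x = np.mgrid[0:L, 0:H, 0:W].astype(float)
    d = peak - ax * (x - cx - x0) ** 2 - ay * (y - cy - y0) ** 2 \
        - al * (l - cl - l0) ** 2
    cfg = st.SiftConfig(n_octaves=1)
    dog = sift.DoGStack([d], cfg)
    return dog, (cl, cy, cx)


class TestRefinement:
    def test_subpixel_fit_matches_analytic_quadratic(self):
        dog, (cl, cy, cx) = quadratic_dog()
        res = st.refine_keypoint((0, cl, cy, cx), dog, 0.04, 10.0)
        assert isinstance(res, st.Keypoint)
        assert res.x_oct == pytest.approx(cx + 0.3, abs=1e-6)
        assert res.y_oct == pytest.approx(cy - 0.2, abs=1e-6)
        assert res.contrast == pytest.approx(0.08, abs=1e-6)

    def test_zero_contrast_candidate_rejected(self):
        dog, (cl, cy, cx) = quadratic_dog(peak=0.0, x0=0.0, y0=0.0, l0=0.0)
        res = st.refine_keypoint((0, cl, cy, cx), dog, 1e-9, 10.0)
        assert res == sift.Rejection("low_contrast")

    def test_default_thresholds_gate_acceptance(self):
        # contrast just below/above the 0.04 default
        dog, c = quadratic_dog(peak=0.039)
        assert st.refine_keypoint((0, *c), dog, 0.04, 10.0) == \
            sift.Rejection("low_contrast")
        dog, c = quadratic_dog(peak=0.041)
        kp = st.refine_keypoint((0, *c), dog, 0.04, 10.0)
        assert isinstance(kp, st.Keypoint) and kp.contrast >= 0.04
        # curvature ratio just above the 10 default (ay/ax > 10)
        dog, c = quadratic_dog(ax=0.001, ay=0.0105)
        assert st.refine_keypoint((0, *c), dog, 0.04, 10.0) == \
            sift.Rejection("edge_like")
        # and just below
        dog, c = quadratic_dog(ax=0.001, ay=0.0095)
        kp = st.refine_keypoint((0, *c), dog, 0.04, 10.0)
        assert isinstance(kp, st.Keypoint)
        assert kp.evr == pytest.approx(9.5, rel=1e-6)

    def test_straight_edge_rejected_for_any_threshold(self):
        # ridge independent of y: one principal curvature exactly zero
        L, H, W = 5, 21, 21
        l, y, x = np.mgrid[0:L, 0:H, 0:W].astype(float)
        d = 0.08 - 0.004 * (x - 10.0) ** 2 - 0.003 * (l - 2.0) ** 2
        dog = sift.DoGStack([d], st.SiftConfig(n_octaves=1))
        res = st.refine_keypoint((0, 2, 10, 10), dog, 0.04, 1e12)
        assert res == sift.Rejection("edge_like")

    def test_runaway_offsets_reported_as_diverged(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(-1, 1, size=(5, 21, 21)) * 1e-3
        # a saddle-ish noisy patch rarely converges from an arbitrary start
        dog = sift.DoGStack([d], st.SiftConfig(n_octaves=1, max_interp_iter=1))
        results = {str(st.refine_keypoint((0, 2, y, x), dog, 0.04, 10.0))
                   for y in range(8, 13) for x in range(8, 13)}
        assert "Rejection(reason='diverged')" in results


class TestOrientation:
    def test_uniform_gradient_gives_single_zero_orientation(self):
        img = np.tile(np.linspace(0, 1, 128), (128, 1))  # gradient along +x
        ss = st.build_scale_space(img, st.SiftConfig(n_octaves=1))
        kp = st.Keypoint(x_oct=64, y_oct=64, octave=0, level=1, sigma=2.0,
                         x_base=64, y_base=64, contrast=0.05, evr=1.0)
        oriented = sift.assign_orientations(kp, ss)
        assert len(oriented) == 1
        assert min(oriented[0].orientation, 360 - oriented[0].orientation) < 1.0

    def test_histogram_has_36_bins(self, phantom_256, detected_256):
        kps, ss, _ = detected_256
        hist = sift.orientation_histogram(kps[0], ss)
        assert hist.shape == (36,)

    def test_two_orthogonal_gradient_populations_give_two_peaks(self):
        # left half: horizontal ramp (0 deg); right half: vertical ramp (90)
        # f = max(x, y): gradient +x below the diagonal, +y above, equal
        # magnitudes, continuous across the kink
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        img = np.maximum(xx, yy) / 127.0
        ss = st.build_scale_space(img, st.SiftConfig(n_octaves=1))
        kp = st.Keypoint(x_oct=64, y_oct=64, octave=0, level=1, sigma=3.0,
                         x_base=64, y_base=64, contrast=0.05, evr=1.0)
        oriented = sift.assign_orientations(kp, ss)
        angles = sorted(k.orientation for k in oriented)
        assert len(angles) == 2
        assert abs((angles[1] - angles[0]) % 360 - 90) < 10

        # independent histogram check: two dominant bins ~9 apart (of 36)
        hist = sift.orientation_histogram(kp, ss)
        top2 = np.argsort(hist)[-2:]
        assert abs(abs(int(top2[0]) - int(top2[1])) - 9) <= 1

    def test_window_fully_outside_raster_gives_empty_list(self, detected_256):
        _, ss, _ = detected_256
        kp = st.Keypoint(x_oct=-500, y_oct=-500, octave=0, level=1, sigma=1.8,
                         x_base=-500, y_base=-500, contrast=0.05, evr=1.0)
        assert sift.assign_orientations(kp, ss) == []


class TestDescriptor:
    def test_flat_patch_gives_zero_descriptor(self):
        ss = st.build_scale_space(np.full((96, 96), 0.5),
                                  st.SiftConfig(n_octaves=1))
        kp = st.Keypoint(x_oct=48, y_oct=48, octave=0, level=1, sigma=2.0,
                         x_base=48, y_base=48, contrast=0.05, evr=1.0,
                         orientation=0.0)
        vec = st.compute_descriptor(kp, ss)
        assert vec.shape == (128,)
        assert np.all(vec == 0)

    def test_descriptors_have_unit_norm(self, phantom_256):
        _, desc, _ = st.detect_and_describe(phantom_256)
        norms = np.linalg.norm(desc, axis=1)
        nondegenerate = norms > 0
        assert nondegenerate.any()
        np.testing.assert_allclose(norms[nondegenerate], 1.0, atol=1e-6)

    def test_descriptor_survives_quarter_turn(self, phantom_256):
        """Keypoints re-detected after a 90 degree rotation should carry
        near-identical descriptors (cosine similarity >= 0.9)."""
        center = ((phantom_256.shape[1] - 1) / 2, (phantom_256.shape[0] - 1) / 2)
        T = st.AffineTransform2D.from_params(0, 0, 90, 1, center=center)
        rotated = st.warp_image(phantom_256, T)
        kps_a, desc_a, _ = st.detect_and_describe(phantom_256)
        kps_b, desc_b, _ = st.detect_and_describe(rotated)
        pts_a = st.map_points(np.array([[k.x_base, k.y_base] for k in kps_a]), T)
        pts_b = np.array([[k.x_base, k.y_base] for k in kps_b])
        sims = []
        for i, p in enumerate(pts_a):
            d = np.linalg.norm(pts_b - p, axis=1)
            j = int(np.argmin(d))
            if d[j] < 2.0:
                na, nb = np.linalg.norm(desc_a[i]), np.linalg.norm(desc_b[j])
                if na > 0 and nb > 0:
                    sims.append(desc_a[i] @ desc_b[j] / (na * nb))
        assert len(sims) >= 5
        assert np.median(sims) >= 0.9


class TestPipeline:
    def test_impossible_contrast_threshold_yields_no_keypoints(self, phantom_256):
        kps, desc, _ = st.detect_and_describe(phantom_256, contrast_thresh=1.0)
        assert kps == [] and desc.shape == (0, 128)

    def test_keypoint_count_monotone_in_thresholds(self, phantom_256):
        n_default = len(st.detect_keypoints(phantom_256, 0.04, 10.0)[0])
        n_strict = len(st.detect_keypoints(phantom_256, 0.06, 8.0)[0])
        assert 0 < n_strict < n_default

    def test_stricter_run_is_subset_of_looser_run(self, phantom_256):
        loose, _, _ = st.detect_keypoints(phantom_256, 0.04, 10.0)
        strict, _, _ = st.detect_keypoints(phantom_256, 0.08, 6.0)
        loose_keys = {(k.octave, k.level, round(k.x_oct, 4), round(k.y_oct, 4))
                      for k in loose}
        strict_keys = {(k.octave, k.level, round(k.x_oct, 4), round(k.y_oct, 4))
                       for k in strict}
        assert strict_keys <= loose_keys

    def test_keypoints_satisfy_their_own_thresholds(self, detected_256):
        kps, _, _ = detected_256
        assert kps
        for k in kps:
            assert k.contrast >= 0.04
            assert 1.0 <= k.evr <= 10.0

    def test_detection_invariant_to_intensity_rescaling(self, phantom_256):
        kps_a, _, _ = st.detect_keypoints(phantom_256)
        rescaled = imgio.normalize01(phantom_256 * 0.5)
        kps_b, _, _ = st.detect_keypoints(rescaled)
        assert [(k.octave, k.x_oct, k.y_oct) for k in kps_a] == \
            [(k.octave, k.x_oct, k.y_oct) for k in kps_b]

    def test_stage_counts_are_conserved(self, phantom_256):
        kps, _, counts = st.detect_keypoints(phantom_256,
                                             assign_orientation=False)
        assert counts["candidates"] == (len(kps) + counts["diverged"]
                                        + counts["low_contrast"]
                                        + counts["edge_like"])

    def test_positions_agree_with_reference_implementation(self, phantom_256):
        """Cross-check diagnostic: at matching parameters, most of our
        keypoints coincide with an independent SIFT implementation."""
        skimage_feature = pytest.importorskip("skimage.feature")
        det = skimage_feature.SIFT(upsampling=1, c_dog=0.04, c_edge=10)
        det.detect(phantom_256)
        ref = det.positions  # (row, col)
        ours, _, _ = st.detect_keypoints(phantom_256)
        pts = np.array([[k.y_base, k.x_base] for k in ours])
        d = np.min(np.linalg.norm(pts[:, None] - ref[None, :], axis=-1), axis=1)
        assert (d <= 2.0).mean() >= 0.70


def test_keypoint_csv_roundtrip(detected_256, tmp_path):
    kps, _, _ = detected_256
    df = sift.keypoints_to_dataframe(kps, image_id="ph1")
    path = tmp_path / "kp.csv"
    df.to_csv(path, index=False)
    import pandas as pd

    back = pd.read_csv(path)
    assert len(back) == len(kps)
    np.testing.assert_allclose(back["x_base"], [k.x_base for k in kps])
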