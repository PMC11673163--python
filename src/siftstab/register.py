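"""Feature-based 2D registration: cross-check matching, 4-DOF similarity
estimation, and difference-image scoring.

Descriptor matches are filtered by mutual nearest neighbors in Euclidean
distance (cross-check), which empirically leaves few outliers without the
ratio test.  The alignment is a limited affine transform with four degrees of
freedom — translation, rotation, uniform scale — solved in closed form and
wrapped in RANSAC, since even cross-checked matches contain occasional
outliers that break unguarded least squares.  Quality is scored as the RMSE
of the difference image over the valid-overlap region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .sift import Keypoint, SiftConfig, detect_and_describe
from .transforms import AffineTransform2D, map_points, warp_image

logger = logging.getLogger(__name__)

DEFAULT_MIN_KEYPOINTS = 10
DEFAULT_GOOD_MATCH_TOL_PX = 5.0
RANSAC_INLIER_TOL_PX = 3.0
RANSAC_ITERATIONS = 1000


class RegistrationError(RuntimeError):
    """Raised when a transform cannot be estimated or scored."""


@dataclass(frozen=True)
class MatchPair:
    ref_index: int
    test_index: int
    descriptor_distance: float
    is_good: bool | None = None  # set when ground truth is known


@dataclass
class RegistrationResult:
    status: str  # "ok" | "too_few_keypoints" | "too_few_matches" | "estimation_failed"
    estimated: AffineTransform2D | None = None
    n_kp_ref: int = 0
    n_kp_test: int = 0
    n_matches: int = 0
    good_match_rate: float = float("nan")
    rmse: float = float("nan")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def cross_check_match(desc_a: np.ndarray, desc_b: np.ndarray) -> list[MatchPair]:
    """Mutual nearest neighbors under Euclidean descriptor distance.

    Equivalent to k=1 matching run in both directions, keeping only
    consistent pairs; equal-distance ties resolve to the lowest index.
    """
    desc_a = np.atleast_2d(np.asarray(desc_a, dtype=float))
    desc_b = np.atleast_2d(np.asarray(desc_b, dtype=float))
    if desc_a.shape[0] == 0 or desc_b.shape[0] == 0:
        return []
    dist = cdist(desc_a, desc_b)
    a_to_b = np.argmin(dist, axis=1)  # argmin takes the lowest index on ties
    b_to_a = np.argmin(dist, axis=0)
    pairs = []
    for i, j in enumerate(a_to_b):
        if b_to_a[j] == i:
            pairs.append(MatchPair(i, int(j), float(dist[i, j])))
    return pairs


def good_match_rate(pairs: list[MatchPair], ref_kps: list[Keypoint],
                    test_kps: list[Keypoint], T_true: AffineTransform2D,
                    tol_px: float = DEFAULT_GOOD_MATCH_TOL_PX) -> float:
    """Fraction of matches consistent with the known ground-truth transform.

    A pair is good when the test keypoint lies within ``tol_px`` (base-image
    pixels) of the mapped reference keypoint.  Zero pairs give rate 0.
    """
    if not pairs:
        return 0.0
    ref_pts = np.array([[ref_kps[p.ref_index].x_base,
                         ref_kps[p.ref_index].y_base] for p in pairs])
    test_pts = np.array([[test_kps[p.test_index].x_base,
                          test_kps[p.test_index].y_base] for p in pairs])
    resid = np.linalg.norm(map_points(ref_pts, T_true) - test_pts, axis=1)
    return float(np.mean(resid < tol_px))


def flag_good_matches(pairs: list[MatchPair], ref_kps, test_kps,
                      T_true: AffineTransform2D,
                      tol_px: float = DEFAULT_GOOD_MATCH_TOL_PX) -> list[MatchPair]:
    """Return pairs with ``is_good`` populated against the ground truth."""
    out = []
    for p in pairs:
        rk, tk = ref_kps[p.ref_index], test_kps[p.test_index]
        mapped = map_points(np.array([[rk.x_base, rk.y_base]]), T_true)[0]
        good = bool(np.hypot(*(mapped - (tk.x_base, tk.y_base))) < tol_px)
        out.append(MatchPair(p.ref_index, p.test_index, p.descriptor_distance, good))
    return out


def _similarity_lsq(src: np.ndarray, dst: np.ndarray) -> AffineTransform2D:
    """Closed-form least-squares similarity fit  dst ≈ s R src + t.

    With demeaned coordinates p, q the optimum is
    a = Σ(p·q)/Σ|p|², b = Σ(p×q)/Σ|p|², s = √(a²+b²), θ = atan2(b, a).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 2:
        raise RegistrationError("need at least 2 point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    p, q = src - mu_s, dst - mu_d
    denom = float((p * p).sum())
    if denom < 1e-12:
        raise RegistrationError("source points are coincident (rank-deficient)")
    a = float((p * q).sum()) / denom
    b = float((p[:, 0] * q[:, 1] - p[:, 1] * q[:, 0]).sum()) / denom
    A = np.array([[a, -b], [b, a]])
    if abs(np.linalg.det(A)) < 1e-12:
        raise RegistrationError("degenerate similarity fit (zero scale)")
    t = mu_d - A @ mu_s
    scale = float(np.hypot(a, b))
    angle = float(np.rad2deg(np.arctan2(b, a)))
    return AffineTransform2D(np.column_stack([A, t]),
                             params=(float(t[0]), float(t[1]), angle, scale),
                             center=(0.0, 0.0))


def estimate_similarity(src: np.ndarray, dst: np.ndarray,
                        robust: bool = True,
                        inlier_tol_px: float = RANSAC_INLIER_TOL_PX,
                        n_iterations: int = RANSAC_ITERATIONS,
                        seed: int = 0) -> tuple[AffineTransform2D, np.ndarray]:
    """4-DOF similarity estimate with RANSAC outlier rejection.

    2-point minimal samples seed closed-form fits; the consensus set refits
    once at the end.  ``robust=False`` gives the plain least-squares solve on
    all pairs.  Returns (transform, inlier mask).
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    n = len(src)
    if n != len(dst):
        raise ValueError("point sets must have equal length")
    if n < 2:
        raise RegistrationError("need at least 2 point pairs")
    if not robust or n == 2:
        T = _similarity_lsq(src, dst)
        resid = np.linalg.norm(map_points(src, T) - dst, axis=1)
        return T, resid < inlier_tol_px

    rng = np.random.default_rng(seed)
    best_inliers = np.zeros(n, dtype=bool)
    for _ in range(n_iterations):
        i, j = rng.choice(n, size=2, replace=False)
        if np.allclose(src[i], src[j]):
            continue
        try:
            T = _similarity_lsq(src[[i, j]], dst[[i, j]])
        except RegistrationError:
            continue
        resid = np.linalg.norm(map_points(src, T) - dst, axis=1)
        inliers = resid < inlier_tol_px
        if inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers.sum() < 2:
        raise RegistrationError("RANSAC found no consensus set")
    T = _similarity_lsq(src[best_inliers], dst[best_inliers])
    resid = np.linalg.norm(map_points(src, T) - dst, axis=1)
    return T, resid < inlier_tol_px


def registration_rmse(ref_img: np.ndarray, test_img: np.ndarray,
                      T_est: AffineTransform2D,
                      full_frame: bool = False) -> float:
    """RMSE of (warp(ref, T_est) - test) over the valid-overlap mask.

    The mask keeps output pixels whose pull-back through T_est lies inside
    the source raster, so border zero-fill does not contaminate the score;
    ``full_frame`` disables the mask for sensitivity analysis.
    """
    ref_img = np.asarray(ref_img, dtype=float)
    test_img = np.asarray(test_img, dtype=float)
    warped = warp_image(ref_img, T_est)
    diff = warped - test_img
    if full_frame:
        return float(np.sqrt(np.mean(diff ** 2)))
    h, w = test_img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    back = map_points(pts, T_est.inverse())
    inside = ((back[:, 0] >= 0) & (back[:, 0] <= w - 1)
              & (back[:, 1] >= 0) & (back[:, 1] <= h - 1)).reshape(h, w)
    if not inside.any():
        raise RegistrationError("empty overlap between warped image and frame")
    return float(np.sqrt(np.mean(diff[inside] ** 2)))


def register_pair(ref_img: np.ndarray, test_img: np.ndarray,
                  contrast_thresh: float = 0.04, evr_thresh: float = 10.0,
                  config: SiftConfig | None = None,
                  T_true: AffineTransform2D | None = None,
                  min_keypoints: int = DEFAULT_MIN_KEYPOINTS,
                  good_match_tol_px: float = DEFAULT_GOOD_MATCH_TOL_PX,
                  robust: bool = True, seed: int = 0) -> RegistrationResult:
    """Full pipeline: detect → describe → cross-check → estimate → score.

    Runs with fewer than ``min_keypoints`` keypoints on either image, or
    where estimation fails, return a failure record rather than raising, so
    threshold sweeps can aggregate them as excluded runs.
    """
    ref_kps, ref_desc, _ = detect_and_describe(ref_img, contrast_thresh,
                                               evr_thresh, config)
    test_kps, test_desc, _ = detect_and_describe(test_img, contrast_thresh,
                                                 evr_thresh, config)
    result = RegistrationResult(status="ok", n_kp_ref=len(ref_kps),
                                n_kp_test=len(test_kps))
    if len(ref_kps) < min_keypoints or len(test_kps) < min_keypoints:
        result.status = "too_few_keypoints"
        return result
    pairs = cross_check_match(ref_desc, test_desc)
    result.n_matches = len(pairs)
    if len(pairs) < 2:
        result.status = "too_few_matches"
        return result
    src = np.array([[ref_kps[p.ref_index].x_base, ref_kps[p.ref_index].y_base]
                    for p in pairs])
    dst = np.array([[test_kps[p.test_index].x_base, test_kps[p.test_index].y_base]
                    for p in pairs])
    try:
        T_est, _ = estimate_similarity(src, dst, robust=robust, seed=seed)
        result.rmse = registration_rmse(ref_img, test_img, T_est)
    except RegistrationError as exc:
        logger.info("registration failed: %s", exc)
        result.status = "estimation_failed"
        return result
    result.estimated = T_est
    if T_true is not None:
        result.good_match_rate = good_match_rate(pairs, ref_kps, test_kps,
                                                 T_true, good_match_tol_px)
    return result
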