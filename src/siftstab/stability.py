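"""Keypoint stability under geometric transformation.

A reference keypoint is *re-detected* under a transform T when, after mapping
its base coordinates by T, some keypoint of the transformed image lies within
a tolerance (default 5 px).  Following the octave-level bookkeeping of the
detector, the distance check is performed on the octave grid of the test
keypoint: base-coordinate residuals are divided by 2^octave_test before the
comparison.  The stability rate of a keypoint is its number of re-detections
divided by the number of transforms applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sift import Keypoint, SiftConfig, detect_keypoints
from .transforms import AffineTransform2D, map_points, warp_image

logger = logging.getLogger(__name__)

DEFAULT_TOL_PX = 5.0


@dataclass(frozen=True)
class StabilityRecord:
    """Re-detection bookkeeping for one reference keypoint."""

    image_id: str
    keypoint: Keypoint
    contrast: float
    evr: float
    occurrences: int
    n_transforms: int

    def __post_init__(self) -> None:
        if not 0 <= self.occurrences <= self.n_transforms:
            raise ValueError("occurrences must lie in [0, n_transforms]")

    @property
    def stability_rate(self) -> float:
        return self.occurrences / self.n_transforms


def correspond(ref_kps: list[Keypoint], T: AffineTransform2D,
               test_kps: list[Keypoint],
               tol_px: float = DEFAULT_TOL_PX) -> np.ndarray:
    """One-to-one re-detection flags for each reference keypoint.

    Reference base coordinates are mapped by T; for a candidate pairing with
    test keypoint j the residual is measured on j's octave grid (divided by
    2^octave_j) and must be strictly below ``tol_px``.  Pairings are assigned
    greedily by ascending distance so no test keypoint is consumed twice.
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be > 0")
    flags = np.zeros(len(ref_kps), dtype=bool)
    if not ref_kps or not test_kps:
        return flags
    ref_pts = np.array([[k.x_base, k.y_base] for k in ref_kps])
    mapped = map_points(ref_pts, T)
    test_pts = np.array([[k.x_base, k.y_base] for k in test_kps])
    grid = np.array([2.0 ** k.octave for k in test_kps])
    # (n_ref, n_test) distances on each test keypoint's octave grid
    diff = mapped[:, None, :] - test_pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1]) / grid[None, :]
    ri, ti = np.nonzero(dist < tol_px)
    order = np.argsort(dist[ri, ti], kind="stable")
    used_test = np.zeros(len(test_kps), dtype=bool)
    for idx in order:
        r, t = ri[idx], ti[idx]
        if flags[r] or used_test[t]:
            continue
        flags[r] = True
        used_test[t] = True
    return flags


def compute_stability(ref_img: np.ndarray,
                      transforms: list[AffineTransform2D],
                      contrast_thresh: float = 0.04,
                      evr_thresh: float = 10.0,
                      config: SiftConfig | None = None,
                      tol_px: float = DEFAULT_TOL_PX,
                      image_id: str = "") -> list[StabilityRecord]:
    """Detect once in the reference and once per warped image; aggregate
    per-keypoint occurrence counts into stability records."""
    if not transforms:
        raise ValueError("at least one transform is required")
    # stability is purely geometric: orientation assignment (which duplicates
    # keypoints at multi-peak locations) is skipped on both sides
    ref_kps, _, _ = detect_keypoints(ref_img, contrast_thresh, evr_thresh,
                                     config, assign_orientation=False)
    if not ref_kps:
        logger.warning("no reference keypoints detected for %r", image_id)
        return []
    occurrences = np.zeros(len(ref_kps), dtype=int)
    for T in transforms:
        warped = warp_image(ref_img, T)
        test_kps, _, _ = detect_keypoints(warped, contrast_thresh, evr_thresh,
                                          config, assign_orientation=False)
        occurrences += correspond(ref_kps, T, test_kps, tol_px)
    return [StabilityRecord(image_id=image_id, keypoint=kp,
                            contrast=kp.contrast, evr=kp.evr,
                            occurrences=int(n), n_transforms=len(transforms))
            for kp, n in zip(ref_kps, occurrences)]


def stability_vs_property(records: list[StabilityRecord]):
    """Correlate stability rate against keypoint contrast and against the
    eigenvalue ratio.  Returns (contrast_report, evr_report)."""
    from .stats import correlation

    if len(records) < 3:
        raise ValueError("need at least 3 records to correlate")
    stab = np.array([r.stability_rate for r in records])
    contrast = np.array([r.contrast for r in records])
    evr = np.array([r.evr for r in records])
    return correlation(contrast, stab), correlation(evr, stab)


def records_to_dataframe(records: list[StabilityRecord]):
    import pandas as pd

    return pd.DataFrame([{
        "image_id": r.image_id,
        "x_base": r.keypoint.x_base, "y_base": r.keypoint.y_base,
        "octave": r.keypoint.octave,
        "contrast": r.contrast, "evr": r.evr,
        "occurrences": r.occurrences, "n_transforms": r.n_transforms,
        "stability_rate": r.stability_rate,
    } for r in records])
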