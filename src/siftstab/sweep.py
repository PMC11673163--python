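"""Study orchestration: dataset construction, threshold sweeps, aggregation.

A *study* is a set of synthetic slices, a shared set of random similarity
transforms, and the grid of warped images.  The sweep varies one detector
threshold at a time (the other held at its default), registers every
(reference, warped) pair at each grid point, and aggregates the median good
match rate, the difference-image RMSE distribution, and the mean keypoint
count normalized to the default-threshold count.  An optional combined run
re-evaluates the per-axis optima jointly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from . import phantom, register, transforms
from .sift import SiftConfig, detect_keypoints

logger = logging.getLogger(__name__)

DEFAULT_CONTRAST = 0.04
DEFAULT_EVR = 10.0
# grids span the threshold values of interest around the defaults
DEFAULT_CONTRAST_GRID = (0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14)
DEFAULT_EVR_GRID = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)


@dataclass(frozen=True)
class SweepConfig:
    contrast_grid: tuple[float, ...] = DEFAULT_CONTRAST_GRID
    evr_grid: tuple[float, ...] = DEFAULT_EVR_GRID
    n_images: int = 10
    n_transforms: int = 12
    image_size: int = 256
    n_structures: int = 6
    noise_sd: float = 0.02
    tol_px: float = 5.0
    min_keypoints: int = 10
    seed: int = 0
    detector: SiftConfig = field(default_factory=SiftConfig)

    def __post_init__(self) -> None:
        for name, grid in (("contrast_grid", self.contrast_grid),
                           ("evr_grid", self.evr_grid)):
            if not grid:
                raise ValueError(f"{name} must be non-empty")
            if list(grid) != sorted(grid):
                raise ValueError(f"{name} must be sorted ascending")
        if DEFAULT_CONTRAST not in self.contrast_grid:
            raise ValueError("contrast_grid must contain the default 0.04 "
                             "(needed for count normalization)")
        if DEFAULT_EVR not in self.evr_grid:
            raise ValueError("evr_grid must contain the default 10 "
                             "(needed for count normalization)")


@dataclass
class Study:
    images: list[np.ndarray]
    transform_sets: list[list[transforms.AffineTransform2D]]
    warped: list[list[np.ndarray]]  # warped[i][t]

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def n_transforms(self) -> int:
        return len(self.transform_sets[0]) if self.transform_sets else 0

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for img in self.images:
            h.update(np.ascontiguousarray(img).tobytes())
        for row in self.warped:
            for img in row:
                h.update(np.ascontiguousarray(img).tobytes())
        return h.hexdigest()


@dataclass
class SweepResult:
    axis: str  # "contrast" | "evr" | "combined"
    contrast_thresh: float
    evr_thresh: float
    median_good_match_rate: float
    rmse_values: list[float]
    median_rmse: float
    keypoint_fraction: float
    n_failed_runs: int
    n_runs: int


def build_study(config: SweepConfig) -> Study:
    """Generate phantoms, draw one shared 12-family transform set, and warp
    every image by every transform (n_images x n_transforms rasters)."""
    base_spec = phantom.PhantomSpec(width=config.image_size,
                                    height=config.image_size,
                                    n_structures=config.n_structures,
                                    noise_sd=config.noise_sd,
                                    seed=config.seed)
    images = phantom.generate_dataset(config.n_images, base_spec)
    specs = transforms.DEFAULT_TRANSFORM_SPECS[:config.n_transforms]
    center = transforms.image_center(images[0].shape)
    # one fixed transform set shared by all images
    tset = transforms.default_transform_set(center, seed=config.seed, specs=specs)
    warped = [[transforms.warp_image(img, T) for T in tset] for img in images]
    return Study(images=images, transform_sets=[tset] * len(images), warped=warped)


def mean_keypoint_count(study: Study, contrast: float, evr: float,
                        config: SweepConfig) -> float:
    counts = [len(detect_keypoints(img, contrast, evr, config.detector)[0])
              for img in study.images]
    return float(np.mean(counts))


def _evaluate_point(study: Study, contrast: float, evr: float,
                    config: SweepConfig, axis: str,
                    default_count: float) -> SweepResult:
    rates, rmses, failed, total = [], [], 0, 0
    for i, img in enumerate(study.images):
        for t, T in enumerate(study.transform_sets[i]):
            total += 1
            res = register.register_pair(
                img, study.warped[i][t], contrast, evr, config.detector,
                T_true=T, min_keypoints=config.min_keypoints,
                good_match_tol_px=config.tol_px, seed=config.seed)
            if not res.ok:
                failed += 1
                continue
            rates.append(res.good_match_rate)
            rmses.append(res.rmse)
    frac = mean_keypoint_count(study, contrast, evr, config) / default_count \
        if default_count > 0 else float("nan")
    return SweepResult(
        axis=axis, contrast_thresh=contrast, evr_thresh=evr,
        median_good_match_rate=float(np.median(rates)) if rates else float("nan"),
        rmse_values=rmses,
        median_rmse=float(np.median(rmses)) if rmses else float("nan"),
        keypoint_fraction=frac, n_failed_runs=failed, n_runs=total)


def run_threshold_sweep(study: Study, config: SweepConfig,
                        combined: bool = True) -> list[SweepResult]:
    """One-axis-at-a-time sweep (other threshold at default), plus an
    optional combined re-run at the per-axis optima."""
    default_count = mean_keypoint_count(study, DEFAULT_CONTRAST, DEFAULT_EVR,
                                        config)
    results: list[SweepResult] = []
    for c in config.contrast_grid:
        results.append(_evaluate_point(study, c, DEFAULT_EVR, config,
                                       "contrast", default_count))
    for e in config.evr_grid:
        results.append(_evaluate_point(study, DEFAULT_CONTRAST, e, config,
                                       "evr", default_count))
    if combined:
        c_best, e_best = select_optimum(results)
        if (c_best, e_best) != (DEFAULT_CONTRAST, DEFAULT_EVR):
            results.append(_evaluate_point(study, c_best, e_best, config,
                                           "combined", default_count))
    return results


def select_optimum(results: list[SweepResult]) -> tuple[float, float]:
    """Per-axis argmin of median RMSE; ties break toward the stricter
    threshold (higher contrast, lower eigenvalue ratio)."""
    def best(axis: str, key, strict_pref):
        pts = [r for r in results if r.axis == axis and np.isfinite(r.median_rmse)]
        if not pts:
            raise ValueError(f"no valid results on the {axis} axis")
        lo = min(r.median_rmse for r in pts)
        tied = [key(r) for r in pts if r.median_rmse <= lo + 1e-12]
        return strict_pref(tied)

    c = best("contrast", lambda r: r.contrast_thresh, max)
    e = best("evr", lambda r: r.evr_thresh, min)
    return c, e


def results_to_dataframe(results: list[SweepResult]):
    import pandas as pd

    return pd.DataFrame([{
        "axis": r.axis, "contrast_thresh": r.contrast_thresh,
        "evr_thresh": r.evr_thresh,
        "median_good_match_rate": r.median_good_match_rate,
        "median_rmse": r.median_rmse,
        "keypoint_fraction": r.keypoint_fraction,
        "n_failed_runs": r.n_failed_runs, "n_runs": r.n_runs,
    } for r in results])
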