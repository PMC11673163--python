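"""Scale-invariant feature transform, implemented from scratch.

The detector follows Lowe's classic pipeline — Gaussian scale-space pyramid,
difference-of-Gaussians (DoG), scale-space extremum detection, quadratic
sub-pixel refinement, contrast and edge-response filtering, orientation
assignment, and 128-d gradient-histogram description — with the two candidate
filters exposed as first-class tunable parameters:

* ``contrast_thresh``: minimum interpolated |D(x̂)| on the [0, 1] intensity
  scale (default 0.04).  NOTE: the threshold is compared to |D(x̂)| directly;
  some implementations divide the threshold by the number of intervals per
  octave first.
* ``evr_thresh``: maximum ratio of the larger to the smaller eigenvalue of
  the 2x2 spatial Hessian of D at the keypoint (default 10).  The actual
  ratio λmax/λmin is stored on every keypoint, not the tr²/det proxy, so it
  can be correlated with downstream stability measurements.

Extremum neighborhoods: both the 26-neighbor L∞ rule (full 3x3x3 cube) and
the 6-neighbor L1 rule (2(n+1) axial neighbors, n=2) are available; L∞ is
the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

FLOAT_TOL = 1e-12


@dataclass(frozen=True)
class SiftConfig:
    """Detector configuration.

    Defaults are Lowe's standard values: base smoothing sigma0=1.6 applied on
    top of an assumed camera blur of 0.5, s=3 intervals per octave, and an
    octave count of floor(log2(min_dim)) - 3 when unset.  No initial 2x
    upsampling is performed unless ``upsample`` is set.
    """

    n_intervals: int = 3
    sigma0: float = 1.6
    n_octaves: int | None = None
    assumed_blur: float = 0.5
    upsample: bool = False
    neighborhood: str = "linf"  # "linf" (26 neighbors) or "l1" (6 neighbors)
    border: int = 5
    max_interp_iter: int = 5
    orientation_bins: int = 36
    peak_ratio: float = 0.8
    orientation_sigma_factor: float = 1.5
    orientation_radius_factor: float = 3.0
    descriptor_width: int = 4
    descriptor_bins: int = 8
    descriptor_scale_multiplier: float = 3.0
    descriptor_clip: float = 0.2

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.neighborhood not in ("linf", "l1"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")

    @property
    def k(self) -> float:
        """Scale factor between adjacent levels within an octave: 2^(1/s)."""
        return 2.0 ** (1.0 / self.n_intervals)


@dataclass(frozen=True)
class Keypoint:
    """A located, scaled, oriented interest point.

    Coordinates use (x=col, y=row) with 0-based pixel centres.  ``x_oct``/
    ``y_oct`` are sub-pixel positions on the grid of the octave where the
    point was detected; base-image coordinates are x_base = x_oct * 2^octave
    (times 0.5 when the pyramid starts from a 2x-upsampled image).
    """

    x_oct: float
    y_oct: float
    octave: int
    level: int
    sigma: float
    x_base: float
    y_base: float
    contrast: float
    evr: float
    orientation: float = float("nan")
    sign: int = 1  # +1 maximum, -1 minimum

    def with_orientation(self, deg: float) -> "Keypoint":
        return replace(self, orientation=float(deg) % 360.0)


@dataclass(frozen=True)
class Rejection:
    reason: str  # "diverged" | "low_contrast" | "edge_like"


class ScaleSpace:
    """Gaussian pyramid: ``octaves[o]`` is an (s+3, H_o, W_o) stack.

    ``sigma(o, i) = sigma0 * 2^o * k^i`` in units of the base image; within
    an octave the smoothing relative to that octave's grid is sigma0 * k^i.
    Per-level gradient fields are computed lazily and cached.
    """

    def __init__(self, octaves: list[np.ndarray], config: SiftConfig,
                 base_scale: float = 1.0):
        self.octaves = octaves
        self.config = config
        self.base_scale = base_scale  # 0.5 if built from a 2x-upsampled image
        self._grad_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)

    def sigma(self, octave: int, level: int) -> float:
        return self.config.sigma0 * (2.0 ** octave) * self.config.k ** level

    def gradients(self, octave: int, level: int) -> tuple[np.ndarray, np.ndarray]:
        """(dx, dy) central-difference gradients of one Gaussian level."""
        key = (octave, level)
        if key not in self._grad_cache:
            L = self.octaves[octave][level]
            dx = np.zeros_like(L)
            dy = np.zeros_like(L)
            dx[:, 1:-1] = 0.5 * (L[:, 2:] - L[:, :-2])
            dy[1:-1, :] = 0.5 * (L[2:, :] - L[:-2, :])
            self._grad_cache[key] = (dx, dy)
        return self._grad_cache[key]


class DoGStack:
    """Difference-of-Gaussians: per octave an (s+2, H_o, W_o) stack,
    D[i] = G[i+1] - G[i]."""

    def __init__(self, octaves: list[np.ndarray], config: SiftConfig):
        self.octaves = octaves
        self.config = config

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)


def _downsample(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    return img[::2, ::2][: h // 2, : w // 2]


def default_n_octaves(shape: tuple[int, int]) -> int:
    return max(1, int(np.floor(np.log2(min(shape[:2])))) - 3)


def build_scale_space(img: np.ndarray, config: SiftConfig | None = None) -> ScaleSpace:
    """Build the Gaussian pyramid: O octaves x (s+3) levels, halving between
    octaves."""
    config = config or SiftConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")

    base_scale = 1.0
    assumed = config.assumed_blur
    if config.upsample:
        img = ndimage.zoom(img, 2.0, order=1)
        assumed *= 2.0
        base_scale = 0.5

    n_oct = config.n_octaves or default_n_octaves(img.shape)
    min_size = 2 * config.border + 3
    if min(img.shape) // (2 ** (n_oct - 1)) < min_size:
        raise ValueError(
            f"image of shape {img.shape} too small for {n_oct} octaves "
            f"(needs >= {min_size} px per side in the top octave)")

    s, sigma0, k = config.n_intervals, config.sigma0, config.k
    base = ndimage.gaussian_filter(
        img, max(np.sqrt(max(sigma0 ** 2 - assumed ** 2, 0.01)), 0.0))

    octaves: list[np.ndarray] = []
    current = base
    for o in range(n_oct):
        levels = [current]
        for i in range(1, s + 3):
            inc = sigma0 * np.sqrt(k ** (2 * i) - k ** (2 * (i - 1)))
            levels.append(ndimage.gaussian_filter(levels[-1], inc))
        octaves.append(np.stack(levels))
        # next octave seeds from the level with twice the base smoothing
        current = _downsample(levels[s])
    return ScaleSpace(octaves, config, base_scale=base_scale)


def build_dog(ss: ScaleSpace) -> DoGStack:
    """Adjacent-level subtraction: s+2 DoG levels per octave."""
    return DoGStack([oct_[1:] - oct_[:-1] for oct_ in ss.octaves], ss.config)


# neighborhood offset tables, (dlevel, dy, dx)
_OFFSETS_LINF = [(dl, dy, dx)
                 for dl in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dl, dy, dx) != (0, 0, 0)]
_OFFSETS_L1 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]

NEIGHBOR_OFFSETS = {"linf": _OFFSETS_LINF, "l1": _OFFSETS_L1}


def detect_extrema(dog: DoGStack, neighborhood: str | None = None,
                   border: int | None = None,
                   prefilter: float = 0.0) -> list[tuple[int, int, int, int]]:
    """Strict local extrema of the DoG stacks.

    Returns (octave, level, y, x) candidates on interior levels (1..s), at
    least ``border`` px from the raster edge.  A candidate must be strictly
    greater than all its neighbors or strictly less than all of them; ties
    are rejected, which avoids duplicate candidates on plateaus.
    ``prefilter`` drops candidates with raw |D| below the given value before
    the comparison (an optimization used by the full pipeline).
    """
    nb = neighborhood or dog.config.neighborhood
    b = dog.config.border if border is None else border
    offsets = NEIGHBOR_OFFSETS[nb]
    out: list[tuple[int, int, int, int]] = []
    for o, d in enumerate(dog.octaves):
        L, H, W = d.shape
        if H <= 2 * b or W <= 2 * b:
            continue
        center = d[1:-1, b:H - b, b:W - b]
        is_max = np.ones(center.shape, dtype=bool)
        is_min = np.ones(center.shape, dtype=bool)
        for dl, dy, dx in offsets:
            nbr = d[1 + dl:L - 1 + dl, b + dy:H - b + dy, b + dx:W - b + dx]
            is_max &= center > nbr
            is_min &= center < nbr
        mask = is_max | is_min
        if prefilter > 0:
            mask &= np.abs(center) >= prefilter
        lv, yy, xx = np.nonzero(mask)
        out.extend(zip([o] * len(lv), (lv + 1).tolist(),
                       (yy + b).tolist(), (xx + b).tolist()))
    return out


def _gradient_hessian_3d(d: np.ndarray, l: int, y: int, x: int):
    """First and second central differences of the DoG cube at (l, y, x),
    ordered (x, y, level)."""
    g = np.array([
        0.5 * (d[l, y, x + 1] - d[l, y, x - 1]),
        0.5 * (d[l, y + 1, x] - d[l, y - 1, x]),
        0.5 * (d[l + 1, y, x] - d[l - 1, y, x]),
    ])
    c = d[l, y, x]
    dxx = d[l, y, x + 1] + d[l, y, x - 1] - 2 * c
    dyy = d[l, y + 1, x] + d[l, y - 1, x] - 2 * c
    dss = d[l + 1, y, x] + d[l - 1, y, x] - 2 * c
    dxy = 0.25 * (d[l, y + 1, x + 1] - d[l, y + 1, x - 1]
                  - d[l, y - 1, x + 1] + d[l, y - 1, x - 1])
    dxs = 0.25 * (d[l + 1, y, x + 1] - d[l + 1, y, x - 1]
                  - d[l - 1, y, x + 1] + d[l - 1, y, x - 1])
    dys = 0.25 * (d[l + 1, y + 1, x] - d[l + 1, y - 1, x]
                  - d[l - 1, y + 1, x] + d[l - 1, y - 1, x])
    H = np.array([[dxx, dxy, dxs],
                  [dxy, dyy, dys],
                  [dxs, dys, dss]])
    return g, H, (dxx, dyy, dxy)


def refine_keypoint(candidate: tuple[int, int, int, int], dog: DoGStack,
                    contrast_thresh: float, evr_thresh: float,
                    config: SiftConfig | None = None,
                    base_scale: float = 1.0) -> Keypoint | Rejection:
    """Quadratic (second-order Taylor) sub-pixel/sub-scale fit plus the
    contrast and edge-response filters.

    Returns an accepted :class:`Keypoint` or a :class:`Rejection` with reason
    ``diverged`` (offset never settled below 0.5), ``low_contrast``
    (|D(x̂)| < contrast_thresh) or ``edge_like`` (indefinite spatial Hessian
    or eigenvalue ratio above evr_thresh).
    """
    config = config or dog.config
    o, l, y, x = candidate
    d = dog.octaves[o]
    L, H, W = d.shape
    b = config.border

    offset = np.zeros(3)
    g = np.zeros(3)
    converged = False
    for _ in range(config.max_interp_iter):
        g, Hm, spatial = _gradient_hessian_3d(d, l, y, x)
        try:
            offset = -np.linalg.solve(Hm, g)
        except np.linalg.LinAlgError:
            # exactly singular (e.g. an ideal ridge): minimal-norm step so the
            # candidate still reaches the contrast/edge filters
            offset = -np.linalg.pinv(Hm, rcond=1e-6) @ g
        if np.all(np.abs(offset) < 0.5):
            converged = True
            break
        x += int(round(offset[0]))
        y += int(round(offset[1]))
        l += int(round(offset[2]))
        if not (1 <= l <= L - 2 and b <= y < H - b and b <= x < W - b):
            return Rejection("diverged")
    if not converged:
        return Rejection("diverged")

    value = d[l, y, x] + 0.5 * float(g @ offset)
    if abs(value) < contrast_thresh:
        return Rejection("low_contrast")

    dxx, dyy, dxy = spatial
    det = dxx * dyy - dxy * dxy
    tr = dxx + dyy
    # a well-localized extremum has a definite spatial Hessian whose sign
    # opposes the extremum value (curving away from a max, toward a min)
    if det <= 0 or tr * value > 0:
        return Rejection("edge_like")
    lam = np.linalg.eigvalsh(np.array([[dxx, dxy], [dxy, dyy]]))
    lam_abs = np.abs(lam)
    if lam_abs.min() < FLOAT_TOL:
        return Rejection("edge_like")
    evr = float(lam_abs.max() / lam_abs.min())
    if evr > evr_thresh:
        return Rejection("edge_like")

    k = config.k
    x_oct = x + float(offset[0])
    y_oct = y + float(offset[1])
    sigma = config.sigma0 * (2.0 ** o) * k ** (l + float(offset[2])) * base_scale
    grid = (2.0 ** o) * base_scale
    return Keypoint(x_oct=x_oct, y_oct=y_oct, octave=o, level=l, sigma=float(sigma),
                    x_base=x_oct * grid, y_base=y_oct * grid,
                    contrast=abs(value), evr=evr,
                    sign=1 if value > 0 else -1)


def _smooth_circular(hist: np.ndarray) -> np.ndarray:
    """One pass of the [1, 4, 6, 4, 1]/16 circular smoothing kernel."""
    n = len(hist)
    idx = np.arange(n)
    return (6 * hist
            + 4 * (hist[(idx - 1) % n] + hist[(idx + 1) % n])
            + (hist[(idx - 2) % n] + hist[(idx + 2) % n])) / 16.0


def orientation_histogram(kp: Keypoint, ss: ScaleSpace) -> np.ndarray | None:
    """36-bin gradient-orientation histogram around a keypoint.

    Samples are weighted by gradient magnitude and a Gaussian circular window
    of width 1.5x the keypoint's octave-level scale.  Returns None when the
    window lies fully outside the raster.
    """
    cfg = ss.config
    o = kp.octave
    gl = int(np.clip(kp.level, 0, ss.octaves[o].shape[0] - 1))
    Himg, Wimg = ss.octaves[o].shape[1:]
    sigma_oct = kp.sigma / ((2.0 ** o) * ss.base_scale)
    win_sigma = cfg.orientation_sigma_factor * sigma_oct
    radius = int(round(cfg.orientation_radius_factor * win_sigma))
    cx, cy = int(round(kp.x_oct)), int(round(kp.y_oct))
    if cx + radius < 0 or cx - radius >= Wimg or cy + radius < 0 or cy - radius >= Himg:
        return None

    y0, y1 = max(cy - radius, 1), min(cy + radius, Himg - 2)
    x0, x1 = max(cx - radius, 1), min(cx + radius, Wimg - 2)
    if y1 < y0 or x1 < x0:
        return None
    dx_full, dy_full = ss.gradients(o, gl)
    dx = dx_full[y0:y1 + 1, x0:x1 + 1]
    dy = dy_full[y0:y1 + 1, x0:x1 + 1]
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    r2 = (xx - kp.x_oct) ** 2 + (yy - kp.y_oct) ** 2
    w = np.exp(-r2 / (2.0 * win_sigma ** 2)) * (r2 <= radius ** 2)
    mag = np.hypot(dx, dy)
    theta = np.rad2deg(np.arctan2(dy, dx)) % 360.0

    nbins = cfg.orientation_bins
    bins = np.round(theta * nbins / 360.0).astype(int) % nbins
    hist = np.bincount(bins.ravel(), weights=(mag * w).ravel(), minlength=nbins)
    return hist


def assign_orientations(kp: Keypoint, ss: ScaleSpace) -> list[Keypoint]:
    """One oriented keypoint per dominant gradient direction.

    Peaks of the smoothed histogram at >= 80% of the maximum each spawn a
    copy; the peak angle is refined by parabolic interpolation over the peak
    bin and its two circular neighbors.
    """
    cfg = ss.config
    hist = orientation_histogram(kp, ss)
    if hist is None:
        return []
    hist = _smooth_circular(hist)
    hmax = hist.max()
    if hmax <= 0:
        return []
    nbins = cfg.orientation_bins
    out = []
    for i in range(nbins):
        hl, hc, hr = hist[(i - 1) % nbins], hist[i], hist[(i + 1) % nbins]
        if hc > hl and hc > hr and hc >= cfg.peak_ratio * hmax:
            denom = hl - 2 * hc + hr
            shift = 0.0 if abs(denom) < FLOAT_TOL else 0.5 * (hl - hr) / denom
            angle = ((i + shift) * 360.0 / nbins) % 360.0
            out.append(kp.with_orientation(angle))
    return out


def compute_descriptor(kp: Keypoint, ss: ScaleSpace) -> np.ndarray | None:
    """128-d descriptor: 4x4 spatial bins x 8 orientation bins, trilinearly
    interpolated, L2-normalized, clamped at 0.2, renormalized.

    Gradients are sampled in a square window around the keypoint rotated by
    its orientation.  Returns None when no valid samples fall inside the
    raster (the keypoint is then dropped by the pipeline).  A flat patch
    yields the all-zero descriptor.
    """
    cfg = ss.config
    if not np.isfinite(kp.orientation):
        raise ValueError("keypoint has no orientation assigned")
    o = kp.octave
    gl = int(np.clip(kp.level, 0, ss.octaves[o].shape[0] - 1))
    Himg, Wimg = ss.octaves[o].shape[1:]
    d = cfg.descriptor_width
    nbins = cfg.descriptor_bins
    sigma_oct = kp.sigma / ((2.0 ** o) * ss.base_scale)
    hist_width = cfg.descriptor_scale_multiplier * sigma_oct
    radius = int(round(hist_width * np.sqrt(2) * (d + 1) * 0.5))
    radius = min(radius, int(np.hypot(Himg, Wimg)))

    cos_t = np.cos(np.deg2rad(kp.orientation))
    sin_t = np.sin(np.deg2rad(kp.orientation))

    offs = np.arange(-radius, radius + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    ox = ox.ravel().astype(float)
    oy = oy.ravel().astype(float)
    # rotate the sampling offsets into the keypoint frame
    x_rot = (ox * cos_t + oy * sin_t) / hist_width
    y_rot = (-ox * sin_t + oy * cos_t) / hist_width
    rbin = y_rot + 0.5 * d - 0.5
    cbin = x_rot + 0.5 * d - 0.5
    px = np.round(kp.x_oct + ox).astype(int)
    py = np.round(kp.y_oct + oy).astype(int)
    valid = ((rbin > -1) & (rbin < d) & (cbin > -1) & (cbin < d)
             & (px >= 1) & (px < Wimg - 1) & (py >= 1) & (py < Himg - 1))
    if not np.any(valid):
        return None
    rbin, cbin = rbin[valid], cbin[valid]
    px, py = px[valid], py[valid]
    x_rot, y_rot = x_rot[valid], y_rot[valid]

    dx_full, dy_full = ss.gradients(o, gl)
    gx = dx_full[py, px]
    gy = dy_full[py, px]
    mag = np.hypot(gx, gy)
    theta = np.rad2deg(np.arctan2(gy, gx)) % 360.0
    weight = np.exp(-(x_rot ** 2 + y_rot ** 2) / (0.5 * d ** 2))
    obin = ((theta - kp.orientation) % 360.0) * nbins / 360.0
    wmag = mag * weight

    hist = np.zeros((d + 2, d + 2, nbins))
    r0 = np.floor(rbin).astype(int)
    c0 = np.floor(cbin).astype(int)
    o0 = np.floor(obin).astype(int)
    rf, cf, of = rbin - r0, cbin - c0, obin - o0
    for dr in (0, 1):
        wr = wmag * (rf if dr else 1 - rf)
        for dc in (0, 1):
            wc = wr * (cf if dc else 1 - cf)
            for do in (0, 1):
                wo = wc * (of if do else 1 - of)
                np.add.at(hist, (r0 + 1 + dr, c0 + 1 + dc, (o0 + do) % nbins), wo)
    vec = hist[1:-1, 1:-1, :].ravel()
    norm = np.linalg.norm(vec)
    if norm < FLOAT_TOL:
        return vec  # degenerate flat patch
    vec = np.minimum(vec / norm, cfg.descriptor_clip)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > FLOAT_TOL else vec


def detect_keypoints(img: np.ndarray, contrast_thresh: float = 0.04,
                     evr_thresh: float = 10.0,
                     config: SiftConfig | None = None,
                     assign_orientation: bool = True,
                     ) -> tuple[list[Keypoint], ScaleSpace, dict[str, int]]:
    """Detection-only pipeline (no descriptors); see
    :func:`detect_and_describe`."""
    config = config or SiftConfig()
    img = np.asarray(img, dtype=float)
    ss = build_scale_space(img, config)
    dog = build_dog(ss)
    # raw-|D| prefilter at half the final threshold: interpolation can raise
    # a candidate's contrast, so the margin keeps the filter conservative
    candidates = detect_extrema(dog, prefilter=0.5 * contrast_thresh)
    counts = {"candidates": len(candidates), "diverged": 0,
              "low_contrast": 0, "edge_like": 0, "no_orientation": 0,
              "accepted": 0}
    kept: list[Keypoint] = []
    seen: set[tuple] = set()
    for cand in candidates:
        res = refine_keypoint(cand, dog, contrast_thresh, evr_thresh,
                              config, base_scale=ss.base_scale)
        if isinstance(res, Rejection):
            counts[res.reason] += 1
            continue
        key = (res.octave, res.level, round(res.x_oct, 1), round(res.y_oct, 1))
        if key in seen:  # two candidates converged to the same point
            continue
        seen.add(key)
        kept.append(res)

    if assign_orientation:
        oriented: list[Keypoint] = []
        for kp in kept:
            owned = assign_orientations(kp, ss)
            if not owned:
                counts["no_orientation"] += 1
            oriented.extend(owned)
        kept = oriented
    kept.sort(key=lambda k: (k.octave, k.level, k.y_oct, k.x_oct, k.orientation))
    counts["accepted"] = len(kept)
    return kept, ss, counts


def detect_and_describe(img: np.ndarray, contrast_thresh: float = 0.04,
                        evr_thresh: float = 10.0,
                        config: SiftConfig | None = None,
                        ) -> tuple[list[Keypoint], np.ndarray, dict[str, int]]:
    """Full pipeline: detect, refine, filter, orient, describe.

    Returns (keypoints, descriptors, stage_counts); descriptors is an
    (n, 128) array row-aligned with the keypoint list.  Keypoints whose
    descriptor window has no valid samples are dropped (counted under
    ``no_descriptor``).
    """
    kps, ss, counts = detect_keypoints(img, contrast_thresh, evr_thresh, config)
    descs: list[np.ndarray] = []
    kept: list[Keypoint] = []
    counts["no_descriptor"] = 0
    for kp in kps:
        vec = compute_descriptor(kp, ss)
        if vec is None:
            counts["no_descriptor"] += 1
            logger.debug("descriptor window outside raster, dropping %s", kp)
            continue
        kept.append(kp)
        descs.append(vec)
    counts["accepted"] = len(kept)
    nbins = (config or SiftConfig()).descriptor_width ** 2 * \
        (config or SiftConfig()).descriptor_bins
    mat = np.vstack(descs) if descs else np.empty((0, nbins))
    return kept, mat, counts


def keypoints_to_dataframe(kps: list[Keypoint], image_id: str = ""):
    """Keypoint list as a DataFrame for CSV export."""
    import pandas as pd

    return pd.DataFrame([{
        "image_id": image_id, "x_base": k.x_base, "y_base": k.y_base,
        "octave": k.octave, "level": k.level, "sigma": k.sigma,
        "contrast": k.contrast, "evr": k.evr, "orientation": k.orientation,
    } for k in kps])
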