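"""Synthetic CBCT-like slice generator.

Real cone-beam CT slices of anatomy show a dark air background, a
mid-intensity soft-tissue body with low-frequency texture, and high-contrast
cortical-bone boundaries (bright rims around marrow-filled interiors).  The
phantoms emulate exactly those three intensity populations so that both blob
responses (bone interiors, texture) and edge responses (cortical rims) are
present — the two keypoint classes the contrast and eigenvalue-ratio filters
act on.  They make the whole pipeline testable without access to clinical
data.

Every phantom is a pure function of its :class:`PhantomSpec`, so a fixed seed
reproduces the raster bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

BACKGROUND_LEVEL = 0.02
BODY_LEVEL = 0.32
TEXTURE_AMPLITUDE = 0.08


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    width, height   raster size in pixels (>= 64 each)
    n_structures    number of bone-like elliptical/annular primitives
    noise_sd        additive Gaussian noise SD on the [0, 1] intensity scale
    texture_scale   correlation length (px) of the soft-tissue texture
    seed            RNG seed; same seed => bit-identical image
    """

    width: int = 512
    height: int = 512
    n_structures: int = 6
    noise_sd: float = 0.02
    texture_scale: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64:
            raise ValueError(f"width must be >= 64, got {self.width}")
        if self.height < 64:
            raise ValueError(f"height must be >= 64, got {self.height}")
        if self.n_structures < 0:
            raise ValueError(f"n_structures must be >= 0, got {self.n_structures}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.texture_scale <= 0:
            raise ValueError(f"texture_scale must be > 0, got {self.texture_scale}")


@dataclass(frozen=True)
class Structure:
    """One bone-like primitive: an ellipse with a bright cortical rim.

    The rim is a Gaussian ridge along the ellipse boundary (elliptical radius
    rho == 1) of amplitude ``rim_amp`` and width ``rim_width`` (in rho units);
    the interior is a smooth plateau of amplitude ``core_amp``.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float  # radians
    rim_amp: float
    rim_width: float
    core_amp: float

    def radial(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx, dy = x - self.cx, y - self.cy
        u = dx * np.cos(self.theta) + dy * np.sin(self.theta)
        v = -dx * np.sin(self.theta) + dy * np.cos(self.theta)
        return np.sqrt((u / self.a) ** 2 + (v / self.b) ** 2)

    def render(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        rho = self.radial(x, y)
        rim = self.rim_amp * np.exp(-0.5 * ((rho - 1.0) / self.rim_width) ** 2)
        core = self.core_amp / (1.0 + np.exp((rho - (1.0 - 2 * self.rim_width)) / 0.04))
        return rim + core


def _body_axes(spec: PhantomSpec) -> tuple[float, float, float, float]:
    cx, cy = (spec.width - 1) / 2.0, (spec.height - 1) / 2.0
    return cx, cy, 0.42 * spec.width, 0.42 * spec.height


def sample_structures(spec: PhantomSpec) -> list[Structure]:
    """Deterministically draw the bone primitives for a spec.

    Exposed so the analytic composite can be re-rendered independently of
    :func:`generate_phantom`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    cx0, cy0, ax0, ay0 = _body_axes(spec)
    min_dim = min(spec.width, spec.height)
    structures = []
    for _ in range(spec.n_structures):
        # keep centres inside ~70% of the body so rims stay in frame
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 1.0)) * 0.65
        cx = cx0 + rad * ax0 * np.cos(ang)
        cy = cy0 + rad * ay0 * np.sin(ang)
        a = rng.uniform(0.05, 0.16) * min_dim
        b = rng.uniform(0.05, 0.16) * min_dim
        theta = rng.uniform(0, np.pi)
        rim_amp = rng.uniform(0.45, 0.65)
        rim_width = rng.uniform(0.04, 0.10)
        core_amp = rng.uniform(0.10, 0.25)
        structures.append(Structure(cx, cy, a, b, theta, rim_amp, rim_width, core_amp))
    return structures


def render_composite(spec: PhantomSpec) -> np.ndarray:
    """The noiseless analytic part of a phantom (background+body+structures)."""
    y, x = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    cx0, cy0, ax0, ay0 = _body_axes(spec)
    body_rho = np.sqrt(((x - cx0) / ax0) ** 2 + ((y - cy0) / ay0) ** 2)
    body = BODY_LEVEL / (1.0 + np.exp((body_rho - 1.0) / 0.02))
    img = BACKGROUND_LEVEL + body
    for s in sample_structures(spec):
        img = img + s.render(x, y)
    return img


def _texture(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    raw = rng.standard_normal((spec.height, spec.width))
    smooth = ndimage.gaussian_filter(raw, spec.texture_scale / 4.0)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * TEXTURE_AMPLITUDE
    # texture only inside the soft-tissue body
    y, x = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    cx0, cy0, ax0, ay0 = _body_axes(spec)
    body_rho = np.sqrt(((x - cx0) / ax0) ** 2 + ((y - cy0) / ay0) ** 2)
    mask = 1.0 / (1.0 + np.exp((body_rho - 0.98) / 0.02))
    return smooth * mask


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom slice on the [0, 1] intensity scale.

    Composite = dark background + soft-tissue body + low-frequency texture
    + n_structures bone-like rim/core primitives + clipped Gaussian noise.
    """
    img = render_composite(spec) + _texture(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 31]))
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 1.0
    return float((a * b).sum() / denom)


def _realize_dataset(n_images: int, base_spec: PhantomSpec,
                     max_ncc: float = 0.95) -> tuple[list[PhantomSpec], list[np.ndarray]]:
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    ss = np.random.SeedSequence(base_spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4 * n_images)]
    images: list[np.ndarray] = []
    specs: list[PhantomSpec] = []
    idx = 0
    while len(images) < n_images:
        if idx >= len(seeds):
            raise RuntimeError("could not generate enough distinct phantoms")
        cand_spec = dataclasses.replace(base_spec, seed=seeds[idx])
        idx += 1
        cand = generate_phantom(cand_spec)
        if all(normalized_cross_correlation(cand, im) < max_ncc for im in images):
            images.append(cand)
            specs.append(cand_spec)
    return specs, images


def generate_dataset(n_images: int, base_spec: PhantomSpec,
                     max_ncc: float = 0.95) -> list[np.ndarray]:
    """Generate ``n_images`` mutually distinct phantoms.

    Seeds are derived from the base spec's seed; any candidate whose
    normalized cross-correlation with an already-accepted image reaches
    ``max_ncc`` is re-drawn with the next derived seed (distinctness guard,
    emulating a slice collection 'as different as possible').
    """
    return _realize_dataset(n_images, base_spec, max_ncc)[1]


def dataset_specs(n_images: int, base_spec: PhantomSpec) -> list[PhantomSpec]:
    """The specs that :func:`generate_dataset` realizes, for manifests."""
    return _realize_dataset(n_images, base_spec)[0]


def save_fixtures(out_dir, n_images: int, base_spec: PhantomSpec) -> None:
    """Write PNG fixtures plus a CSV manifest (seed, size, parameters)."""
    import csv
    import pathlib

    import imageio.v3 as iio

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs, images = _realize_dataset(n_images, base_spec)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "seed", "width", "height", "n_structures",
                         "noise_sd", "texture_scale"])
        for i, (spec, img) in enumerate(zip(specs, images)):
            name = f"phantom_{i:03d}.png"
            iio.imwrite(out / name, (np.clip(img, 0, 1) * 65535).astype(np.uint16))
            writer.writerow([name, spec.seed, spec.width, spec.height,
                             spec.n_structures, spec.noise_sd, spec.texture_scale])
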