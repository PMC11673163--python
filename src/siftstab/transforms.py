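"""Randomized 2D similarity transforms: sampling, composition, image/point warping.

The benchmark deforms each reference slice with transforms drawn from twelve
parameter families (pure translation, small/large rotation, up/down scaling,
and their combinations).  All transforms are similarities (4 degrees of
freedom: tx, ty, angle, uniform scale) built about the image centre, so that
rotated/scaled content stays comparable to the reference frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AffineTransform2D:
    """A 2x3 affine map acting on (x, y) base-image coordinates.

    ``matrix`` maps the column vector (x, y, 1) to (x', y').  When the
    transform was built from similarity parameters, ``params`` holds
    (tx, ty, angle_deg, scale) and ``center`` the (cx, cy) pivot.
    """

    matrix: np.ndarray
    params: tuple[float, float, float, float] | None = None
    center: tuple[float, float] | None = None
    transform_id: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("transform is singular (det of linear part ~ 0)")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
                   params=(0.0, 0.0, 0.0, 1.0), center=(0.0, 0.0))

    @classmethod
    def from_params(cls, tx: float, ty: float, angle_deg: float, scale: float,
                    center: tuple[float, float] = (0.0, 0.0),
                    transform_id: str | None = None) -> "AffineTransform2D":
        """Similarity about ``center``: scale, then rotate, then translate.

        x' = s R (x - c) + c + t
        """
        if scale == 0:
            raise ValueError("scale must be nonzero")
        th = np.deg2rad(angle_deg)
        A = scale * np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        t = c - A @ c + np.array([tx, ty], dtype=float)
        return cls(np.column_stack([A, t]),
                   params=(float(tx), float(ty), float(angle_deg), float(scale)),
                   center=(float(c[0]), float(c[1])), transform_id=transform_id)

    # -- algebra -----------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform2D(np.column_stack([Ainv, -Ainv @ self.translation]))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        A = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return AffineTransform2D(np.column_stack([A, t]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def params_about(self, center: tuple[float, float]) -> tuple[float, float, float, float]:
        """Decompose into (tx, ty, angle_deg, scale) about the given pivot.

        Only meaningful for similarity matrices (uniform scale, no shear).
        """
        A = self.linear
        scale = float(np.sqrt(abs(np.linalg.det(A))))
        angle = float(np.rad2deg(np.arctan2(A[1, 0], A[0, 0])))
        c = np.asarray(center, dtype=float)
        t = self.translation + A @ c - c
        return float(t[0]), float(t[1]), angle, scale

    def to_dict(self) -> dict:
        return {
            "id": self.transform_id,
            "params": list(self.params) if self.params else None,
            "center": list(self.center) if self.center else None,
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(np.array(d["matrix"], dtype=float),
                   params=tuple(d["params"]) if d.get("params") else None,
                   center=tuple(d["center"]) if d.get("center") else None,
                   transform_id=d.get("id"))


@dataclass(frozen=True)
class TransformSpec:
    """Parameter ranges defining one transform family.

    Each range is an inclusive (lo, hi) interval; degenerate families fix a
    parameter with lo == hi.
    """

    id: str
    tx_range: tuple[float, float] = (0.0, 0.0)
    ty_range: tuple[float, float] = (0.0, 0.0)
    angle_range: tuple[float, float] = (0.0, 0.0)
    scale_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("tx_range", "ty_range", "angle_range", "scale_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well ordered: {(lo, hi)}")
        lo, hi = self.scale_range
        if lo <= 0 <= hi:
            raise ValueError("scale_range must exclude 0")


# The 12 benchmark families: translation-only, small/large rotations,
# up/down scalings, and their combinations.
DEFAULT_TRANSFORM_SPECS: tuple[TransformSpec, ...] = (
    TransformSpec("T0", (-10, 10), (-10, 10), (0, 0), (1, 1)),
    TransformSpec("T1", (0, 0), (0, 0), (1, 5), (1, 1)),
    TransformSpec("T2", (0, 0), (0, 0), (30, 45), (1, 1)),
    TransformSpec("T3", (-10, 10), (-10, 10), (1, 5), (1, 1)),
    TransformSpec("T4", (0, 0), (0, 0), (0, 0), (1.1, 1.5)),
    TransformSpec("T5", (0, 0), (0, 0), (0, 0), (0.7, 0.9)),
    TransformSpec("T6", (-10, 10), (-10, 10), (0, 0), (1.1, 1.5)),
    TransformSpec("T7", (-10, 10), (-10, 10), (0, 0), (0.7, 0.9)),
    TransformSpec("T8", (0, 0), (0, 0), (1, 5), (1.1, 1.5)),
    TransformSpec("T9", (0, 0), (0, 0), (30, 45), (0.7, 0.9)),
    TransformSpec("T10", (-10, 10), (-10, 10), (1, 5), (1.1, 1.5)),
    TransformSpec("T11", (-10, 10), (-10, 10), (1, 5), (0.7, 0.9)),
)


def sample_transform(spec: TransformSpec, center: tuple[float, float],
                     rng_seed: int | np.random.Generator,
                     integer_params: bool = False) -> AffineTransform2D:
    """Draw one transform from a family, uniformly over each parameter range.

    Parameters are continuous by default; ``integer_params`` switches to
    integer-lattice draws for the translation/rotation ranges.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    def draw(lo: float, hi: float, integral: bool) -> float:
        if lo == hi:
            return float(lo)
        if integral:
            return float(rng.integers(int(lo), int(hi), endpoint=True))
        return float(rng.uniform(lo, hi))

    tx = draw(*spec.tx_range, integer_params)
    ty = draw(*spec.ty_range, integer_params)
    ang = draw(*spec.angle_range, integer_params)
    sc = draw(*spec.scale_range, False)
    return AffineTransform2D.from_params(tx, ty, ang, sc, center=center,
                                         transform_id=spec.id)


def default_transform_set(center: tuple[float, float], seed: int,
                          specs: tuple[TransformSpec, ...] = DEFAULT_TRANSFORM_SPECS,
                          ) -> list[AffineTransform2D]:
    """One sample from each of the 12 families, in order, seed-deterministic."""
    rng = np.random.default_rng(seed)
    return [sample_transform(s, center, rng) for s in specs]


def image_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Centre of an (h, w) raster in (x, y) pixel-centre coordinates."""
    h, w = shape[:2]
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def warp_image(img: np.ndarray, T: AffineTransform2D) -> np.ndarray:
    """Warp by inverse mapping with bilinear interpolation; outside = 0.

    The output raster has the same shape as the input; each output pixel is
    pulled from T^-1 of its location.
    """
    img = np.asarray(img, dtype=float)
    inv = T.inverse()
    # scipy works in (row, col); our matrices act on (x, y) = (col, row).
    A = inv.linear
    Arc = np.array([[A[1, 1], A[1, 0]], [A[0, 1], A[0, 0]]])
    orc = np.array([inv.translation[1], inv.translation[0]])
    return ndimage.affine_transform(img, Arc, offset=orc, order=1,
                                    mode="constant", cval=0.0)


def map_points(points: np.ndarray, T: AffineTransform2D) -> np.ndarray:
    """Exact matrix application to (x, y) base-image coordinates."""
    return T.apply(points)


def save_transform_set(transforms: list[AffineTransform2D], path, seed: int | None = None) -> None:
    payload = {"seed": seed, "transforms": [t.to_dict() for t in transforms]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_transform_set(path) -> list[AffineTransform2D]:
    with open(path) as fh:
        payload = json.load(fh)
    return [AffineTransform2D.from_dict(d) for d in payload["transforms"]]
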