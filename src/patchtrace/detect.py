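"""Gaussian-blob "virtual" particle detection on binary frames.

Instead of segmenting individual cells, the pipeline samples the foreground
with blob particles of an expected diameter ``d`` (Crocker–Grier style):
band-pass the mask, keep well-separated local maxima, reject low-mass
candidates, refine each center to sub-pixel precision by iterated
intensity-weighted centroids. Detection runs on the binary mask, so mass
counts foreground pixels under the blob footprint. Choosing ``d`` below the
smallest cell dimension guarantees every cell holds at least one (typically
about two) particles, which is the regime the trajectory and patch stages
assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.spatial import cKDTree

from .frames import BinaryFrame

__all__ = [
    "CellGeometry",
    "DetectionParams",
    "Particle",
    "expected_diameter",
    "detect_particles",
]


@dataclass(frozen=True)
class CellGeometry:
    """Average cell dimensions in image space (px)."""

    l: float  # noqa: E741 - field name mirrors common usage (length)
    w: float

    def __post_init__(self) -> None:
        if not (self.l >= self.w > 0):
            raise ValueError(f"need length >= width > 0, got {self.l}, {self.w}")


@dataclass(frozen=True)
class DetectionParams:
    """Blob diameter ``d`` (odd, px), minimum center separation, mass floor.

    Defaults derived from ``d``: separation = d, minmass = a quarter of the
    area of a disc of diameter d (a blob must cover at least a quarter of
    its nominal footprint with foreground).
    """

    d: int
    separation: float | None = None
    minmass: float | None = None

    def __post_init__(self) -> None:
        if self.d < 3 or self.d % 2 == 0:
            raise ValueError(f"d must be an odd integer >= 3, got {self.d}")
        if self.separation is not None and self.separation <= 0:
            raise ValueError("separation must be > 0")

    @property
    def sep(self) -> float:
        return float(self.d) if self.separation is None else float(self.separation)

    @property
    def mass_floor(self) -> float:
        if self.minmass is not None:
            return float(self.minmass)
        return 0.25 * math.pi * (self.d / 2.0) ** 2


@dataclass(frozen=True)
class Particle:
    """One detected blob: frame index, per-frame index, sub-pixel center."""

    t: int
    p: int
    x: float
    y: float
    mass: float


def expected_diameter(geom: CellGeometry) -> int:
    """Expected particle diameter from the average cell geometry.

    For anisotropic cells the candidate scales are the two cell dimensions
    and half their difference; the diameter is the largest odd integer not
    exceeding the smallest candidate, never below 3. For round cells the
    candidates are the width and half the width. Keeping ``d`` under the
    minimum cell dimension is what makes the ≥1-particle-per-cell guarantee
    hold.
    """
    big, small = max(geom.l, geom.w), min(geom.l, geom.w)
    if geom.l != geom.w:
        candidates = (big, small, 0.5 * (big - small))
    else:
        candidates = (geom.w, 0.5 * geom.w)
    target = max(3.0, min(candidates))
    d = int(math.floor(target))
    if d % 2 == 0:
        d -= 1
    return max(3, d)


def _bandpass(img: np.ndarray, d: int) -> np.ndarray:
    """Gaussian (scale d/4) minus boxcar (width d) background, clipped >= 0."""
    smoothed = gaussian_filter(img, sigma=d / 4.0, mode="constant")
    background = uniform_filter(img, size=d, mode="constant")
    return np.clip(smoothed - background, 0.0, None)


def detect_particles(
    mask: BinaryFrame, params: DetectionParams
) -> list[Particle]:
    """Detect particles on one binary frame; deterministic, empty-safe."""
    img = mask.mask.astype(float)
    if not img.any():
        return []
    bp = _bandpass(img, params.d)

    # candidate maxima: pixels that are the max of their separation window
    from scipy.ndimage import maximum_filter

    win = 2 * int(math.ceil(params.sep)) + 1
    peaks = (bp >= maximum_filter(bp, size=win, mode="constant")) & (bp > 1e-12)
    ys, xs = np.nonzero(peaks)
    if ys.size == 0:
        return []
    vals = bp[ys, xs]
    # brighter first; ties broken by scan order (y, then x) for determinism
    order = np.lexsort((xs, ys, -vals))
    ys, xs = ys[order], xs[order]

    kept: list[tuple[int, int]] = []
    tree_pts: list[tuple[float, float]] = []
    sep2 = params.sep**2
    for y, x in zip(ys, xs):
        ok = True
        for ky, kx in kept:
            if (ky - y) ** 2 + (kx - x) ** 2 < sep2:
                ok = False
                break
        if ok:
            kept.append((int(y), int(x)))
            tree_pts.append((float(x), float(y)))
    if not kept:
        return []

    h, w = img.shape
    rad = params.d / 2.0
    r_int = int(math.ceil(rad))
    offs = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disc = offs[0] ** 2 + offs[1] ** 2 <= rad**2

    particles: list[Particle] = []
    idx = 0
    for y0, x0 in kept:
        mass = _disc_sum(img, y0, x0, offs, disc)
        if mass < params.mass_floor:
            continue
        cy, cx = _refine_centroid(bp, float(y0), float(x0), offs, disc)
        cx = float(np.clip(cx, 0.0, w - 1.0))
        cy = float(np.clip(cy, 0.0, h - 1.0))
        particles.append(Particle(t=mask.time_index, p=idx, x=cx, y=cy, mass=mass))
        idx += 1
    return particles


def _disc_sum(img, y0, x0, offs, disc) -> float:
    h, w = img.shape
    yy = offs[0][disc] + y0
    xx = offs[1][disc] + x0
    valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    return float(img[yy[valid], xx[valid]].sum())


def _refine_centroid(bp, y, x, offs, disc, max_iter: int = 10, tol: float = 5e-3):
    """Iterated intensity-weighted centroid within the blob footprint."""
    h, w = bp.shape
    for _ in range(max_iter):
        yi, xi = int(round(y)), int(round(x))
        yy = offs[0][disc] + yi
        xx = offs[1][disc] + xi
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yy, xx = yy[valid], xx[valid]
        weights = bp[yy, xx]
        total = weights.sum()
        if total <= 0:
            break
        ny = float((weights * yy).sum() / total)
        nx = float((weights * xx).sum() / total)
        if math.hypot(ny - y, nx - x) < tol:
            y, x = ny, nx
            break
        y, x = ny, nx
    return y, x


def particles_to_dataframe(particles: list[Particle]):
    """Flat table: frame, p, x, y, mass."""
    import pandas as pd

    return pd.DataFrame(
        [dict(frame=q.t, p=q.p, x=q.x, y=q.y, mass=q.mass) for q in particles]
    )


def nearest_particle_distance(particles: list[Particle]) -> float:
    """Smallest center-to-center distance among particles of one frame."""
    if len(particles) < 2:
        return math.inf
    pts = np.array([[q.x, q.y] for q in particles])
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].min())
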