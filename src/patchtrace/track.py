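"""Linking particles into trajectories, filtering, and color attachment.

Frame-to-frame linking in the Crocker–Grier tradition: candidate matches
are particle pairs within the search radius ``sigma_max`` found through a
KD-tree; within each connected candidate subnetwork the assignment
minimizing the total squared displacement is chosen (an unfilled link costs
``sigma_max**2``); a trajectory losing its particle stays open for up to
``W_max`` frames before terminating, so cells whose fluorescence briefly
drops out are not lost. There is no motion model: colony growth, not
ballistic motion, drives the displacements.

Short trajectories (span below ``W_min`` frames) are treated as spurious
and removed. Surviving trajectories are re-associated with fluorescence by
sampling the RGB channels at each particle position, normalized linearly by
the global per-channel minimum and maximum across the whole movie;
completely black points (all three normalized channels exactly 0) are the
global-background signature and are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .detect import Particle
from .frames import Frame

log = logging.getLogger(__name__)

__all__ = [
    "LinkingParams",
    "ParticleTrajectory",
    "FeatureVector",
    "default_linking_params",
    "link_particles",
    "filter_trajectories",
    "attach_colors",
]

#: subnetworks with more track+particle nodes fall back to greedy linking
SUBNET_CAP = 24

_BIG = 1e12


@dataclass(frozen=True)
class LinkingParams:
    sigma_max: float  # search radius, px
    W_max: int  # memory: frames a lost trajectory stays open
    W_min: int  # minimum trajectory span, frames

    def __post_init__(self) -> None:
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be > 0")
        if self.W_max < 0 or self.W_min < 1:
            raise ValueError("need W_max >= 0 and W_min >= 1")


@dataclass(frozen=True)
class FeatureVector:
    """Position plus normalized color of one particle at one frame."""

    t: int
    x: float
    y: float
    r: float
    g: float
    b: float


@dataclass
class ParticleTrajectory:
    """Time-ordered track of one particle, with colors once attached."""

    k: int
    points: list[tuple[int, float, float]] = field(default_factory=list)
    features: list[tuple[float, float, float]] | None = None

    @property
    def t_first(self) -> int:
        return self.points[0][0]

    @property
    def t_last(self) -> int:
        return self.points[-1][0]

    @property
    def span(self) -> int:
        """Frames between first and last observation, inclusive."""
        return self.t_last - self.t_first + 1

    def point_at(self, t: int) -> tuple[float, float] | None:
        for pt, px, py in self.points:
            if pt == t:
                return (px, py)
        return None

    def feature_vectors(self) -> list[FeatureVector]:
        if self.features is None:
            raise ValueError(f"trajectory {self.k} has no colors attached")
        return [
            FeatureVector(t, x, y, *rgb)
            for (t, x, y), rgb in zip(self.points, self.features)
        ]


def default_linking_params(d: int, frame_count: int) -> LinkingParams:
    """Defaults tied to the blob diameter and the movie length.

    Search radius ``d - 2`` px; memory 15% of the frame count; minimum span
    10% of the frame count (at least 1).
    """
    if d < 3:
        raise ValueError("d must be >= 3")
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    return LinkingParams(
        sigma_max=float(d - 2),
        W_max=math.floor(0.15 * frame_count),
        W_min=max(1, math.floor(0.10 * frame_count)),
    )


class _Track:
    __slots__ = ("points", "last_xy", "last_t")

    def __init__(self, t: int, x: float, y: float):
        self.points = [(t, x, y)]
        self.last_xy = (x, y)
        self.last_t = t

    def add(self, t: int, x: float, y: float) -> None:
        self.points.append((t, x, y))
        self.last_xy = (x, y)
        self.last_t = t


def link_particles(
    particles_by_frame: list[list[Particle]], params: LinkingParams
) -> list[ParticleTrajectory]:
    """Link per-frame particle lists into disjoint trajectories.

    Frames are taken in list order (frame index = position). The output
    trajectories are disjoint by construction: every particle observation
    belongs to exactly one trajectory.
    """
    finished: list[_Track] = []
    active: list[_Track] = []
    for t, particles in enumerate(particles_by_frame):
        still_active = []
        for tr in active:
            if tr.last_t >= t - 1 - params.W_max:
                still_active.append(tr)
            else:
                finished.append(tr)
        active = still_active

        pts = [(float(q.x), float(q.y)) for q in particles]
        matches = _assign(active, pts, params)
        matched_particles = set()
        for ti, pi in matches:
            active[ti].add(t, *pts[pi])
            matched_particles.add(pi)
        for pi, (x, y) in enumerate(pts):
            if pi not in matched_particles:
                active.append(_Track(t, x, y))
    finished.extend(active)
    finished.sort(key=lambda tr: (tr.points[0][0], tr.points[0][2], tr.points[0][1]))
    return [
        ParticleTrajectory(k=k, points=list(tr.points))
        for k, tr in enumerate(finished)
    ]


def _assign(
    active: list[_Track], pts: list[tuple[float, float]], params: LinkingParams
) -> list[tuple[int, int]]:
    """Match active tracks to current-frame particles.

    Candidate pairs lie within ``sigma_max``; connected candidate
    subnetworks are solved optimally (minimum total squared displacement
    with an unfilled-link cost of ``sigma_max**2``), with a greedy
    nearest-first fallback for oversized subnetworks.
    """
    if not active or not pts:
        return []
    sigma2 = params.sigma_max**2
    track_xy = np.array([tr.last_xy for tr in active])
    pts_arr = np.array(pts)
    tree_p = cKDTree(pts_arr)
    cand: dict[int, list[tuple[int, float]]] = {}
    for ti, xy in enumerate(track_xy):
        for pi in tree_p.query_ball_point(xy, params.sigma_max):
            d2 = float((pts_arr[pi, 0] - xy[0]) ** 2 + (pts_arr[pi, 1] - xy[1]) ** 2)
            cand.setdefault(ti, []).append((pi, d2))
    if not cand:
        return []

    # connected subnetworks over the bipartite candidate graph
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(a):
        while parent.setdefault(a, a) != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for ti, plist in cand.items():
        for pi, _ in plist:
            union(("t", ti), ("p", pi))
    groups: dict[tuple[str, int], tuple[list[int], set[int]]] = {}
    for ti in cand:
        root = find(("t", ti))
        groups.setdefault(root, ([], set()))[0].append(ti)
        for pi, _ in cand[ti]:
            groups[root][1].add(pi)

    matches: list[tuple[int, int]] = []
    for tis, pis_set in groups.values():
        tis = sorted(tis)
        pis = sorted(pis_set)
        if len(tis) + len(pis) > SUBNET_CAP:
            log.warning(
                "linking subnetwork with %d tracks / %d particles exceeds cap; "
                "using greedy nearest-first assignment",
                len(tis),
                len(pis),
            )
            matches.extend(_greedy(tis, pis, cand))
            continue
        matches.extend(_optimal(tis, pis, cand, sigma2))
    return matches


def _optimal(tis, pis, cand, sigma2) -> list[tuple[int, int]]:
    nt, npart = len(tis), len(pis)
    pi_index = {pi: j for j, pi in enumerate(pis)}
    n = nt + npart
    cost = np.full((n, n), _BIG)
    for i, ti in enumerate(tis):
        for pi, d2 in cand[ti]:
            cost[i, pi_index[pi]] = d2
        cost[i, npart + i] = sigma2  # track goes unmatched
    for j in range(npart):
        cost[nt + j, j] = sigma2  # particle starts a new track
    cost[nt:, npart:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    out = []
    for i, j in zip(rows, cols):
        if i < nt and j < npart and cost[i, j] < _BIG:
            out.append((tis[i], pis[j]))
    return out


def _greedy(tis, pis, cand) -> list[tuple[int, int]]:
    edges = sorted(
        (d2, ti, pi) for ti in tis for pi, d2 in cand[ti]
    )
    used_t: set[int] = set()
    used_p: set[int] = set()
    out = []
    for d2, ti, pi in edges:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        out.append((ti, pi))
    return out


def filter_trajectories(
    trajs: list[ParticleTrajectory], W_min: int
) -> list[ParticleTrajectory]:
    """Drop trajectories spanning fewer than ``W_min`` frames; keep order."""
    if W_min < 1:
        raise ValueError("W_min must be >= 1")
    return [tr for tr in trajs if tr.span >= W_min]


def attach_colors(
    trajs: list[ParticleTrajectory],
    rgb_frames: list[Frame],
    contrast: float = 0.0,
    sample_radius: float = 0.0,
    sample_stat: str = "mean",
) -> list[ParticleTrajectory]:
    """Sample and normalize fluorescence for every trajectory point.

    Channels are sampled at the rounded particle position — or, when
    ``sample_radius`` > 0, aggregated over a disc of that radius with
    ``sample_stat`` (``"mean"`` damps pixel-level jitter; ``"max"`` reads
    each channel's emission peak within the blob, which keeps particles at
    cell rims and junctions at their cell's plateau intensity instead of
    the boundary falloff) — and rescaled as
    ``255 * (v - min_c) / (max_c - min_c)`` with extrema taken over every
    pixel of every frame. Points whose normalized color is exactly
    (0, 0, 0) are dropped; trajectories emptied by the drop are removed.
    A globally constant channel maps to 0 everywhere (logged).

    ``contrast`` > 0 applies a logistic contrast curve after the linear
    rescale, decreasing low and intensifying high fluorescence. Pixels at
    the boundary between differently fluorescing cells blend the two
    emissions, and the resulting gradient of intermediate colors can chain
    distinct subpopulations together under the transitive patch decision;
    the contrast step snaps intermediate values toward the extremes so a
    sharp expression difference stays sharp at the particle level.
    ``contrast = 0`` is the identity; around 15 the curve is strongly
    sigmoidal.
    """
    stacks = {
        c: np.stack([np.asarray(f.channels[c], dtype=float) for f in rgb_frames])
        for c in ("r", "g", "b")
    }
    lo = {c: s.min() for c, s in stacks.items()}
    hi = {c: s.max() for c, s in stacks.items()}
    for c in ("r", "g", "b"):
        if hi[c] == lo[c]:
            log.warning("channel %r is globally constant; it normalizes to 0", c)

    def stretch(v: float) -> float:
        if contrast <= 0:
            return v
        z = 1.0 / (1.0 + math.exp(-contrast * (v / 255.0 - 0.5)))
        z0 = 1.0 / (1.0 + math.exp(contrast * 0.5))
        return 255.0 * (z - z0) / (1.0 - 2.0 * z0)

    if sample_radius > 0:
        r_int = int(math.ceil(sample_radius))
        oy, ox = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
        in_disc = oy**2 + ox**2 <= sample_radius**2
        disc = (oy[in_disc], ox[in_disc])
    else:
        disc = None

    out: list[ParticleTrajectory] = []
    for tr in trajs:
        points: list[tuple[int, float, float]] = []
        feats: list[tuple[float, float, float]] = []
        for t, x, y in tr.points:
            h, w = rgb_frames[t].shape
            xi = int(np.clip(round(x), 0, w - 1))
            yi = int(np.clip(round(y), 0, h - 1))
            if disc is not None:
                yy = np.clip(disc[0] + yi, 0, h - 1)
                xx = np.clip(disc[1] + xi, 0, w - 1)
            rgb = []
            for c in ("r", "g", "b"):
                if hi[c] == lo[c]:
                    rgb.append(0.0)
                else:
                    if disc is None:
                        v = stacks[c][t, yi, xi]
                    elif sample_stat == "max":
                        v = float(stacks[c][t, yy, xx].max())
                    else:
                        v = float(stacks[c][t, yy, xx].mean())
                    rgb.append(255.0 * (v - lo[c]) / (hi[c] - lo[c]))
            if rgb[0] == 0.0 and rgb[1] == 0.0 and rgb[2] == 0.0:
                continue  # completely black particle: background signature
            points.append((t, x, y))
            feats.append((stretch(rgb[0]), stretch(rgb[1]), stretch(rgb[2])))
        if points:
            out.append(ParticleTrajectory(k=tr.k, points=points, features=feats))
    return out


def trajectories_to_dataframe(trajs: list[ParticleTrajectory]):
    """Flat table: k, t, x, y (and r, g, b where attached)."""
    import pandas as pd

    rows = []
    for tr in trajs:
        for i, (t, x, y) in enumerate(tr.points):
            row = dict(k=tr.k, t=t, x=x, y=y)
            if tr.features is not None:
                row.update(zip("rgb", tr.features[i]))
            rows.append(row)
    return pd.DataFrame(rows)
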