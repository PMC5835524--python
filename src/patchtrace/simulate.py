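"""Synthetic colony-movie generator with ground truth.

Emulates time-lapse fluorescence movies of a rod-shaped bacterial
monolayer: cells are ellipses rendered with a sigmoid intensity profile,
they elongate exponentially and divide at a length threshold, a damped
pairwise-repulsion relaxation keeps the monolayer overlap-free (the
microfluidic membrane prevents cells from stacking), and per-cell discrete
fluorescence states map to RGB colors so that simulated subpopulations have
known ground truth. All randomness flows through one seeded generator.
"""

from __future__ import annotations

import math
import warnings
from copy import deepcopy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.affinity import rotate, scale, translate
from shapely.geometry import Point

from .frames import Frame

__all__ = [
    "SimCell",
    "SimConfig",
    "GroundTruth",
    "step_growth",
    "relax_positions",
    "render_frame",
    "simulate_movie",
]

#: default fluorescence states and their RGB emission colors
DEFAULT_STATE_COLORS = {
    "red": (210.0, 40.0, 40.0),
    "green": (40.0, 210.0, 40.0),
}


@dataclass
class SimCell:
    """One elliptical cell: geometry plus a discrete fluorescence state."""

    id: int
    parent_id: int | None
    center: tuple[float, float]  # (x, y) in px
    length: float  # major axis, px
    width: float  # minor axis, px
    orientation: float  # radians, CCW from +x
    fluor_state: str
    rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"cell {self.id}: need length >= width > 0, "
                f"got {self.length}, {self.width}"
            )
        if any(not (0 <= c <= 255) for c in self.rgb):
            raise ValueError(f"cell {self.id}: rgb out of [0, 255]: {self.rgb}")

    @property
    def area(self) -> float:
        return math.pi * self.length * self.width / 4.0

    def radius_along(self, ux: float, uy: float) -> float:
        """Ellipse radius in the direction of unit vector (ux, uy)."""
        a, b = self.length / 2.0, self.width / 2.0
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        # component of the direction along/perpendicular to the major axis
        ca = ux * c + uy * s
        sa = -ux * s + uy * c
        return a * b / math.hypot(b * ca, a * sa)

    def polygon(self, segments: int = 24):
        """Shapely polygon approximating the ellipse outline."""
        circ = Point(0.0, 0.0).buffer(1.0, quad_segs=max(4, segments // 4))
        ell = scale(circ, self.length / 2.0, self.width / 2.0)
        ell = rotate(ell, self.orientation, use_radians=True)
        return translate(ell, self.center[0], self.center[1])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated movie.

    The defaults describe a 25-frame movie (one frame per 30 min) of a
    colony founded by two cells, with one doubling per five frames — a
    realistic division time of ~2.5 h for a slow-growing rod — reaching
    roughly 50 cells in the final frame.
    """

    frame_count: int = 25
    image_size: tuple[int, int] = (300, 300)  # (H, W) px
    initial_cells: int = 2
    growth_rate: float = 2.0 ** (1.0 / 5.0) - 1.0  # fraction of length/frame
    division_length: float = 44.0  # px
    initial_length: float = 24.0  # px
    cell_width: float = 11.0  # px
    state_switch_prob: float = 0.0  # per cell per frame
    noise_sigma: float = 6.0  # additive Gaussian, intensity units
    sigmoid_steepness: float = 10.0
    relax_iterations: int = 60
    seed: int = 0
    orientation_jitter: float = 0.15  # rad std-dev at division
    division_asymmetry: float = 0.05  # std-dev of the daughter length split
    max_overlap_frac: float = 0.05  # tolerated pairwise overlap/min area
    state_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_COLORS)
    )
    founder_positions: tuple[tuple[float, float], ...] | None = None
    founder_states: tuple[str, ...] | None = None
    founder_orientations: tuple[float, ...] | None = None
    #: deterministic switches: (frame, cell_id, new_state); applied to the
    #: cell and all of its living descendants at that frame
    programmed_switches: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if not (0.0 <= self.state_switch_prob <= 1.0):
            raise ValueError("state_switch_prob must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.state_colors)


@dataclass
class GroundTruth:
    """Per-frame cell snapshots plus division and state-switch events."""

    snapshots: list[list[SimCell]] = field(default_factory=list)
    #: (frame, parent_id, child1_id, child2_id)
    divisions: list[tuple[int, int, int, int]] = field(default_factory=list)
    #: (frame, cell_id, old_state, new_state)
    switches: list[tuple[int, int, str, str]] = field(default_factory=list)
    parent_map: dict[int, int | None] = field(default_factory=dict)

    def cells_at(self, t: int) -> list[SimCell]:
        return self.snapshots[t]

    def founder_of(self, cell_id: int) -> int:
        cur = cell_id
        while self.parent_map.get(cur) is not None:
            cur = self.parent_map[cur]
        return cur

    def n_families(self) -> int:
        last = self.snapshots[-1]
        return len({self.founder_of(c.id) for c in last})

    def descendants_and_self(self, cell_id: int, alive: list[SimCell]) -> list[SimCell]:
        out = []
        for c in alive:
            cur: int | None = c.id
            while cur is not None:
                if cur == cell_id:
                    out.append(c)
                    break
                cur = self.parent_map.get(cur)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t, cells in enumerate(self.snapshots):
            for c in cells:
                rows.append(
                    dict(
                        frame=t,
                        id=c.id,
                        parent_id=-1 if c.parent_id is None else c.parent_id,
                        x=c.center[0],
                        y=c.center[1],
                        length=c.length,
                        width=c.width,
                        orientation=c.orientation,
                        state=c.fluor_state,
                        r=c.rgb[0],
                        g=c.rgb[1],
                        b=c.rgb[2],
                    )
                )
        return pd.DataFrame(rows)


def step_growth(
    cells: list[SimCell], config: SimConfig, rng: np.random.Generator
) -> tuple[list[SimCell], list[tuple[int, int, int]], list[tuple[int, str, str]]]:
    """Elongate every cell, divide the long ones, maybe switch states.

    Each length is multiplied by ``1 + growth_rate``. A cell reaching
    ``division_length`` is replaced by two half-length daughters placed
    end-to-end along the parent axis (orientation jittered). Returns the new
    cell list, division triples ``(parent, child1, child2)`` and switch
    tuples ``(cell, old_state, new_state)``.
    """
    next_id = max((c.id for c in cells), default=-1) + 1
    grown: list[SimCell] = []
    divisions: list[tuple[int, int, int]] = []
    for cell in cells:
        new_len = cell.length * (1.0 + config.growth_rate)
        if new_len >= config.division_length:
            # slightly asymmetric division desynchronizes the cell cycle
            frac = 0.5
            if config.division_asymmetry > 0:
                frac = float(
                    np.clip(rng.normal(0.5, config.division_asymmetry), 0.35, 0.65)
                )
            ux, uy = math.cos(cell.orientation), math.sin(cell.orientation)
            kids = []
            for sign, part in ((-1.0, frac), (1.0, 1.0 - frac)):
                jitter = (
                    rng.normal(0.0, config.orientation_jitter)
                    if config.orientation_jitter > 0
                    else 0.0
                )
                # daughter center: midpoint of its share of the parent rod
                off = sign * (1.0 - part) * new_len / 2.0
                kids.append(
                    SimCell(
                        id=next_id,
                        parent_id=cell.id,
                        center=(
                            cell.center[0] + off * ux,
                            cell.center[1] + off * uy,
                        ),
                        length=part * new_len,
                        width=cell.width,
                        orientation=cell.orientation + jitter,
                        fluor_state=cell.fluor_state,
                        rgb=cell.rgb,
                    )
                )
                next_id += 1
            divisions.append((cell.id, kids[0].id, kids[1].id))
            grown.extend(kids)
        else:
            grown.append(replace(cell, length=new_len))

    switches: list[tuple[int, str, str]] = []
    if config.state_switch_prob > 0 and len(config.states) > 1:
        for cell in grown:
            if rng.random() < config.state_switch_prob:
                others = [s for s in config.states if s != cell.fluor_state]
                new_state = others[rng.integers(len(others))]
                switches.append((cell.id, cell.fluor_state, new_state))
                cell.fluor_state = new_state
                cell.rgb = tuple(config.state_colors[new_state])
    return grown, divisions, switches


def _clamp_into_image(cell: SimCell, config: SimConfig) -> None:
    h, w = config.image_size
    m = cell.width / 2.0
    x = min(max(cell.center[0], m), w - 1 - m)
    y = min(max(cell.center[1], m), h - 1 - m)
    cell.center = (x, y)


def relax_positions(cells: list[SimCell], config: SimConfig) -> list[SimCell]:
    """Push overlapping ellipse pairs apart along their center axis.

    Damped pairwise-repulsion sweeps, at most ``relax_iterations`` of them;
    the monolayer constraint is met when every pairwise ellipse-overlap area
    is at most ``max_overlap_frac`` of the smaller cell's area. Failing that
    after the final sweep raises a warning, not an error. Deterministic:
    no randomness is consumed.
    """
    cells = [replace(c) for c in cells]
    for c in cells:
        _clamp_into_image(c, config)
    if len(cells) < 2:
        return cells

    push_tol = 0.4 * config.max_overlap_frac  # aim comfortably under the limit
    polys = [c.polygon() for c in cells]
    areas = [c.area for c in cells]
    for _ in range(config.relax_iterations):
        centers = np.array([c.center for c in cells])
        reach = max(c.length for c in cells)
        tree = cKDTree(centers)
        pairs = sorted(tree.query_pairs(reach))
        moved = False
        for i, j in pairs:
            ci, cj = cells[i], cells[j]
            dx = cj.center[0] - ci.center[0]
            dy = cj.center[1] - ci.center[1]
            dist = math.hypot(dx, dy)
            if dist > (ci.length + cj.length) / 2.0:
                continue
            inter = polys[i].intersection(polys[j]).area
            small = min(areas[i], areas[j])
            if inter <= push_tol * small:
                continue
            if dist < 1e-9:
                ux, uy = math.cos(ci.orientation), math.sin(ci.orientation)
            else:
                ux, uy = dx / dist, dy / dist
            pen = ci.radius_along(ux, uy) + cj.radius_along(ux, uy) - dist
            step = 0.6 * max(pen, 0.2 * min(ci.width, cj.width))
            ci.center = (ci.center[0] - 0.5 * step * ux, ci.center[1] - 0.5 * step * uy)
            cj.center = (cj.center[0] + 0.5 * step * ux, cj.center[1] + 0.5 * step * uy)
            _clamp_into_image(ci, config)
            _clamp_into_image(cj, config)
            polys[i] = ci.polygon()
            polys[j] = cj.polygon()
            moved = True
        if not moved:
            break

    worst = _worst_overlap_fraction(cells)
    if worst > config.max_overlap_frac:
        warnings.warn(
            f"relaxation left a pairwise overlap of {worst:.1%} of the smaller "
            f"cell after {config.relax_iterations} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    return cells


def _worst_overlap_fraction(cells: list[SimCell]) -> float:
    if len(cells) < 2:
        return 0.0
    centers = np.array([c.center for c in cells])
    tree = cKDTree(centers)
    polys = [c.polygon() for c in cells]
    worst = 0.0
    for i, j in tree.query_pairs(max(c.length for c in cells)):
        inter = polys[i].intersection(polys[j]).area
        worst = max(worst, inter / min(cells[i].area, cells[j].area))
    return worst


def render_frame(
    cells: list[SimCell], config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one (H, W, 3) uint8 frame.

    Each cell contributes ``rgb / (1 + exp(k * (rho - 1)))`` per pixel,
    where ``rho`` is the normalized elliptical distance (1 on the cell
    boundary) and ``k`` the sigmoid steepness; contributions combine by
    per-channel maximum, then Gaussian noise is added and the result is
    clipped to [0, 255]. Noise-free rendering is deterministic and
    independent of cell-list order.
    """
    h, w = config.image_size
    img = np.zeros((h, w, 3), dtype=float)
    k = config.sigmoid_steepness
    for cell in cells:
        a, b = cell.length / 2.0, cell.width / 2.0
        ext = a * (1.0 + 8.0 / k) + 2.0
        cx, cy = cell.center
        x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 2)
        y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        co, si = math.cos(cell.orientation), math.sin(cell.orientation)
        u = (xx - cx) * co + (yy - cy) * si
        v = -(xx - cx) * si + (yy - cy) * co
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        prof = 1.0 / (1.0 + np.exp(np.clip(k * (rho - 1.0), -50.0, 50.0)))
        for ch in range(3):
            np.maximum(
                img[y0:y1, x0:x1, ch], cell.rgb[ch] * prof, out=img[y0:y1, x0:x1, ch]
            )
    if config.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        img += rng.normal(0.0, config.noise_sigma, img.shape)
    np.clip(np.rint(img), 0, 255, out=img)
    return img.astype(np.uint8)


def _init_founders(config: SimConfig, rng: np.random.Generator) -> list[SimCell]:
    h, w = config.image_size
    n = config.initial_cells
    if min(h, w) < 2 * config.initial_length:
        raise ValueError(
            f"image {config.image_size} too small for cells of length "
            f"{config.initial_length}"
        )
    if config.founder_positions is not None:
        if len(config.founder_positions) != n:
            raise ValueError("founder_positions length must equal initial_cells")
        positions = [tuple(map(float, p)) for p in config.founder_positions]
    else:
        positions = []
        min_sep = 2.0 * config.initial_length
        lo_x, hi_x = 0.25 * w, 0.75 * w
        lo_y, hi_y = 0.25 * h, 0.75 * h
        for _ in range(n):
            for _attempt in range(200):
                cand = (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
                if all(math.dist(cand, p) >= min_sep for p in positions):
                    positions.append(cand)
                    break
            else:
                raise ValueError("could not place founders without crowding")
    if config.founder_orientations is not None:
        orientations = list(config.founder_orientations)
    else:
        orientations = [rng.uniform(0.0, math.pi) for _ in range(n)]
    states = list(
        config.founder_states
        if config.founder_states is not None
        else [config.states[i % len(config.states)] for i in range(n)]
    )
    cells = []
    for i in range(n):
        cells.append(
            SimCell(
                id=i,
                parent_id=None,
                center=positions[i],
                length=config.initial_length,
                width=config.cell_width,
                orientation=orientations[i],
                fluor_state=states[i],
                rgb=tuple(config.state_colors[states[i]]),
            )
        )
    return cells


def simulate_movie(config: SimConfig) -> tuple[list[Frame], GroundTruth]:
    """Run the full simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cells = _init_founders(config, rng)
    cells = relax_positions(cells, config)
    gt = GroundTruth()
    gt.parent_map.update({c.id: c.parent_id for c in cells})
    frames: list[Frame] = []
    for t in range(config.frame_count):
        if t > 0:
            cells, divisions, switches = step_growth(cells, config, rng)
            for parent, c1, c2 in divisions:
                gt.divisions.append((t, parent, c1, c2))
            for cell in cells:
                gt.parent_map.setdefault(cell.id, cell.parent_id)
            for cid, old, new in switches:
                gt.switches.append((t, cid, old, new))
            for frame_at, target, new_state in config.programmed_switches:
                if frame_at != t:
                    continue
                for cell in gt.descendants_and_self(target, cells):
                    if cell.fluor_state != new_state:
                        gt.switches.append((t, cell.id, cell.fluor_state, new_state))
                        cell.fluor_state = new_state
                        cell.rgb = tuple(config.state_colors[new_state])
            cells = relax_positions(cells, config)
        gt.snapshots.append(deepcopy(cells))
        img = render_frame(cells, config, rng if config.noise_sigma > 0 else None)
        frames.append(
            Frame(t, {"r": img[..., 0], "g": img[..., 1], "b": img[..., 2]})
        )
    return frames, gt
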