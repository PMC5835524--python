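"""Canned ground-truthed study scenarios.

Each scenario couples a simulator configuration to the analysis parameters
a practitioner would choose for it, and returns everything needed to score
the pipeline against the simulation's ground truth. They are used by the
examples, the test suite and the reproduction script.

Scale rationale (same for all three): cells are elongated rods (width
11 px, dividing at 44 px), so the expected particle diameter from the
average geometry is 9 px; colonies reach ~20-50 cells over 25 frames
(one doubling per five frames); the patch distance threshold is chosen at
roughly a third of the final colony diameter, mirroring the ratio used on
real chamber recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .patches import final_patches, lineage_families
from .pipeline import PipelineResult, RunConfig, analyze_movie
from .simulate import GroundTruth, SimConfig, simulate_movie

#: median distance from a detected particle center to the cell outline,
#: measured on one isolated noise-free rendered cell (d = 9, width 11 px)
PARTICLE_INSET_PX = 3.1

__all__ = [
    "ScenarioResult",
    "separated_colonies",
    "switch_colony",
    "meeting_colonies",
    "subpopulation_summary",
    "family_union_time",
    "cross_family_edges",
]


@dataclass
class ScenarioResult:
    config: SimConfig
    ground_truth: GroundTruth
    pipeline: PipelineResult
    #: scenario-specific ground-truth quantity (switch frame, contact frame, ...)
    truth: dict

    @property
    def graph(self) -> nx.MultiDiGraph:
        return self.pipeline.lineage.graph


def _founder_side(gt: GroundTruth, cell_id: int) -> int:
    return gt.founder_of(cell_id)


def separated_colonies(seed: int = 0) -> ScenarioResult:
    """Two well-separated colonies with distinct fixed colors.

    The colonies never touch, so the lineage should resolve exactly two
    final patches — one family per colony — covering essentially all
    trajectory points.
    """
    cfg = SimConfig(
        seed=seed,
        frame_count=25,
        image_size=(420, 420),
        initial_cells=2,
        founder_positions=((110.0, 210.0), (310.0, 210.0)),
        founder_states=("red", "green"),
        state_switch_prob=0.0,
    )
    frames, gt = simulate_movie(cfg)
    result = analyze_movie(frames, _scenario_run(t_d=60.0))
    return ScenarioResult(cfg, gt, result, truth={"n_subpopulations": 2})


def switch_colony(seed: int = 0, switch_frame: int = 16) -> ScenarioResult:
    """One colony, two subpopulations, one programmed state switch.

    Two founders of different states grow side by side as one colony. At
    ``switch_frame`` the red-lineage cell closest to the green
    subpopulation switches to green (descendants inherit it). A pilot run
    of the identical simulation — programmed switches consume no random
    numbers, so cell ids and positions are reproducible — picks the
    switching cell. The backward split pass should cut the switched
    trajectories' red history off their green patch within one frame of
    the switch.
    """
    base = SimConfig(
        seed=seed,
        frame_count=25,
        image_size=(380, 380),
        initial_cells=2,
        founder_positions=((155.0, 190.0), (225.0, 190.0)),
        founder_states=("red", "green"),
        state_switch_prob=0.0,
    )
    _, pilot_gt = simulate_movie(base)
    # pick the switching lineage a few frames before the event so that the
    # switched subtree holds several particles (a coherent group) at the
    # switch; descendants inherit the programmed state
    pick_frame = max(0, switch_frame - 6)
    cells = pilot_gt.cells_at(pick_frame)
    greens = [c for c in cells if pilot_gt.founder_of(c.id) == 1]
    green_cx = float(np.mean([c.center[0] for c in greens]))
    green_cy = float(np.mean([c.center[1] for c in greens]))
    reds = [c for c in cells if pilot_gt.founder_of(c.id) == 0]
    target = min(
        reds, key=lambda c: math.hypot(c.center[0] - green_cx, c.center[1] - green_cy)
    )
    cfg = replace(base, programmed_switches=((switch_frame, target.id, "green"),))
    frames, gt = simulate_movie(cfg)
    result = analyze_movie(frames, _scenario_run(t_d=60.0))
    return ScenarioResult(
        cfg, gt, result, truth={"switch_frame": switch_frame, "switch_cell": target.id}
    )


def meeting_colonies(seed: int = 0) -> ScenarioResult:
    """Two same-colored colonies that grow into contact.

    Founders 170 px apart expand toward each other; near contact the gap
    closes by tens of pixels per frame, so the first frame at which the
    colony outlines touch is sharp. The forward merge pass should join the
    two colony patches within one frame of that contact. The ground-truth
    contact frame is computed from the simulated cell outlines.
    """
    cfg = SimConfig(
        seed=seed,
        frame_count=25,
        image_size=(440, 380),
        initial_cells=2,
        founder_positions=((135.0, 190.0), (305.0, 190.0)),
        founder_orientations=(0.0, 0.0),
        founder_states=("red", "red"),
        state_switch_prob=0.0,
    )
    frames, gt = simulate_movie(cfg)
    # the colonies share one color, so the color tests carry no
    # information and are disabled (thresholds at the 255 maximum, the
    # channel-ignoring trick); the default linking radius (d - 2) applies,
    # and a tight distance threshold makes the contact frame sharp
    run = RunConfig(d=9, t_d=30.0, t_r=255.0, t_g=255.0, t_b=255.0)
    # colonies are in patch-joining range once their outlines approach
    # within t_d minus twice the particle inset (particle centers sit
    # about 3 px inside the cell boundary for this geometry; see the
    # methods note for the calibration)
    contact = _contact_frame(gt, run.t_d - 2.0 * PARTICLE_INSET_PX)
    result = analyze_movie(frames, run)
    return ScenarioResult(cfg, gt, result, truth={"contact_frame": contact})


def _scenario_run(t_d: float) -> RunConfig:
    """Analysis parameters shared by the scenarios.

    The blob diameter follows from the cell geometry (9 px for these
    rods). The linking radius is widened beyond the d-2 default because
    colony expansion moves rim particles by up to ~12 px between frames;
    the default would fragment their tracks. Colors use the contrast
    normalization (boundary pixels between differently colored cells blend
    both emissions; the contrast step keeps expression differences sharp),
    tight thresholds on the informative red and green channels, and the
    blue channel — homogeneous across these simulations — is ignored by
    setting its threshold to the maximum.
    """
    return RunConfig(
        d=9, sigma_max=12.0, t_d=t_d,
        t_r=30.0, t_g=30.0, t_b=255.0,
        color_contrast=15.0, color_sample_radius=4.5, color_sample_stat="max",
    )


def _contact_frame(gt: GroundTruth, reach: float) -> int | None:
    """First frame at which the two families' outlines come within ``reach``."""
    for t, cells in enumerate(gt.snapshots):
        fams = {}
        for c in cells:
            fams.setdefault(gt.founder_of(c.id), []).append(c)
        if len(fams) < 2:
            continue
        a, b = (fams[f] for f in sorted(fams))
        pa = [c.polygon() for c in a]
        pb = [c.polygon() for c in b]
        if any(x.distance(y) < reach for x in pa for y in pb):
            return t
    return None


def _point_families(res: ScenarioResult) -> dict[tuple[int, int], int]:
    """Founder family of every trajectory point (via the nearest true cell)."""
    gt = res.ground_truth
    out: dict[tuple[int, int], int] = {}
    for tr in res.pipeline.trajectories:
        for t, x, y in tr.points:
            cells = gt.cells_at(t)
            nearest = min(
                cells, key=lambda c: (c.center[0] - x) ** 2 + (c.center[1] - y) ** 2
            )
            out[(tr.k, t)] = gt.founder_of(nearest.id)
    return out


def family_union_time(res: ScenarioResult) -> int | None:
    """First frame at which the two founder colonies are joined.

    Two mechanisms can join them: a forward merge event between patches of
    different families, or — when the colonies stay connected through the
    movie end — a single final-frame patch carrying both, whose
    pre-contact history the backward split pass cut off. The union time is
    the earlier of (a) the first cross-family merge event and (b) the
    first frame where the dominant patch of each family coincides in the
    post-split (pre-merge) assignment, which contains no whole-lifespan
    relabels and therefore dates the events correctly.
    """
    fams = _point_families(res)
    pre = res.pipeline.lineage.pre_merge
    family_of = _patch_families(res)

    candidates: list[int] = []
    for absorbed, absorber, t in res.pipeline.lineage.assignment.merge_events:
        fa, fb = family_of.get(absorbed), family_of.get(absorber)
        if fa is not None and fb is not None and fa != fb:
            candidates.append(t)
            break

    by_frame: dict[int, dict[int, dict[int, int]]] = {}
    for (k, t), fam in fams.items():
        j = pre.assign[(k, t)]
        by_frame.setdefault(t, {}).setdefault(fam, {}).setdefault(j, 0)
        by_frame[t][fam][j] += 1
    for t in sorted(by_frame):
        per_fam = by_frame[t]
        if len(per_fam) < 2:
            continue
        dominants = {
            fam: max(counts, key=lambda j: (counts[j], -j))
            for fam, counts in per_fam.items()
        }
        vals = list(dominants.values())
        if all(v == vals[0] for v in vals):
            candidates.append(t)
            break
    return min(candidates) if candidates else None


def _patch_families(res: ScenarioResult) -> dict[int, int]:
    """Majority founder family per patch ID, from the pre-merge assignment."""
    fams = _point_families(res)
    pre = res.pipeline.lineage.pre_merge
    votes: dict[int, dict[int, int]] = {}
    for (k, t), fam in fams.items():
        j = pre.assign[(k, t)]
        votes.setdefault(j, {}).setdefault(fam, 0)
        votes[j][fam] += 1
    return {j: max(f, key=lambda x: (f[x], -x)) for j, f in votes.items()}


def cross_family_edges(res: ScenarioResult) -> list[tuple[int, int, int]]:
    """Graph edges joining the two founder families: (source, target, t).

    Each patch is attributed to the family holding the majority of its
    points; edges between patches of different families mark union events.
    """
    family_of = _patch_families(res)
    out = []
    for u, v, attrs in res.graph.edges(data=True):
        if family_of.get(u) != family_of.get(v):
            out.append((u, v, attrs["t"]))
    return sorted(out, key=lambda e: e[2])


def subpopulation_summary(res: ScenarioResult) -> dict:
    """Final patches, their families and point coverage for a scenario."""
    graph = res.graph
    finals = final_patches(graph)
    families = lineage_families(graph)
    total = sum(a["n_points"] for _, a in graph.nodes(data=True))
    covered_nodes = set().union(*families.values()) if families else set()
    covered = sum(a["n_points"] for n, a in graph.nodes(data=True) if n in covered_nodes)
    return {
        "final_patches": finals,
        "n_final": len(finals),
        "coverage": covered / total if total else 0.0,
        "n_nodes": graph.number_of_nodes(),
    }
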