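"""Patch finding and the patch-lineage construction passes.

A *patch* is a set of spatially contiguous particles at one frame with
mutually similar positions and fluorescence under the decision function
Phi: the product of four strict indicator tests, one on Euclidean distance
(threshold ``t_d``) and one per color channel (``t_r``, ``t_g``, ``t_b``).
Patches at a frame are the connected components of the Phi similarity
graph (single-linkage transitive closure).

The lineage is built in three propagation passes over the particle
trajectories:

1. *Upstream propagation* — patches are found once, at the final frame
   (where the colony is largest), and each trajectory alive there carries
   its final-frame patch ID back to all its earlier points; a trajectory
   absent from the final frame receives a fresh ID.
2. *Split pass* (backward) — within each patch at each frame, membership is
   re-examined: members that re-cluster into several Phi components, or
   whose own features jump by at least a color threshold between this frame
   and the next, are split into new patches at this and all earlier frames.
3. *Merge pass* (forward, mirroring biological growth) — patch pairs whose
   oriented bounding rectangles intersect merge when some cross-pair of
   members is Phi-similar; patches with disjoint lifespans separated by at
   most ``delta_t`` frames merge when they overlap geometrically at their
   temporal boundary and agree in mean color (the merge-window case).

The result is a directed acyclic graph of patch lifespans with split and
merge edges — the subpopulation history of the colony.

Patch IDs: the final-frame patches are labeled 1..C (component order by
the minimum (y, x) member); fresh IDs — for trajectories absent at the
final frame and for split products — take the smallest unused value
starting from 0, so the first trajectory that is new with respect to the
final frame gets ID 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import count

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import concave_hull, obb_distance
from .track import FeatureVector, ParticleTrajectory

__all__ = [
    "PatchThresholds",
    "PatchAssignment",
    "phi",
    "find_patches",
    "propagate_upstream",
    "split_pass",
    "merge_pass",
    "build_lineage_graph",
    "compute_patch_lineage",
    "final_patches",
    "lineage_families",
    "family_point_coverage",
    "six_track_example",
]


@dataclass(frozen=True)
class PatchThresholds:
    """Strict user thresholds of the decision function plus the merge window."""

    t_d: float  # px
    t_r: float = 50.0
    t_g: float = 50.0
    t_b: float = 50.0
    delta_t: int = 3  # frames

    def __post_init__(self) -> None:
        if min(self.t_d, self.t_r, self.t_g, self.t_b) < 0 or self.delta_t < 0:
            raise ValueError("all thresholds must be >= 0")

    def colors_similar(self, a, b) -> bool:
        return (
            abs(a[0] - b[0]) < self.t_r
            and abs(a[1] - b[1]) < self.t_g
            and abs(a[2] - b[2]) < self.t_b
        )


def phi(v: FeatureVector, v2: FeatureVector, th: PatchThresholds) -> int:
    """Decision function: 1 iff all four strict threshold tests pass."""
    if math.hypot(v.x - v2.x, v.y - v2.y) >= th.t_d:
        return 0
    if abs(v.r - v2.r) >= th.t_r:
        return 0
    if abs(v.g - v2.g) >= th.t_g:
        return 0
    if abs(v.b - v2.b) >= th.t_b:
        return 0
    return 1


def find_patches(points: list[FeatureVector], th: PatchThresholds) -> np.ndarray:
    """Patch label per point: connected components of the Phi graph.

    All points must share one frame. Labels start at 1 and are assigned in
    increasing order of each component's minimum (y, x) point, so the
    labeling is deterministic; label 0 is reserved for patches created
    later during upstream propagation.
    """
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=int)
    frames = {p.t for p in points}
    if len(frames) > 1:
        raise ValueError(f"points span multiple frames: {sorted(frames)}")
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    xy = np.array([[p.x, p.y] for p in points])
    if th.t_d > 0:
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(th.t_d):
            if math.hypot(*(xy[i] - xy[j])) >= th.t_d:  # strict inequality
                continue
            a, b = points[i], points[j]
            if th.colors_similar((a.r, a.g, a.b), (b.r, b.g, b.b)):
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb

    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    comps = sorted(
        roots.values(), key=lambda idx: min((points[i].y, points[i].x) for i in idx)
    )
    labels = np.zeros(n, dtype=int)
    for lbl, idx in enumerate(comps, start=1):
        for i in idx:
            labels[i] = lbl
    return labels


# ---------------------------------------------------------------------------
# assignment container


@dataclass
class PatchAssignment:
    """Mutable map (trajectory ID, frame) -> patch ID, plus the event log."""

    assign: dict[tuple[int, int], int] = field(default_factory=dict)
    #: (patch keeping its ID, freshly created ID, frame)
    split_events: list[tuple[int, int, int]] = field(default_factory=list)
    #: (absorbed ID, absorbing ID, frame)
    merge_events: list[tuple[int, int, int]] = field(default_factory=list)

    def ids(self) -> set[int]:
        return set(self.assign.values())

    def members_at(self, t: int) -> dict[int, list[int]]:
        """patch ID -> trajectory IDs with a point assigned at frame t."""
        out: dict[int, list[int]] = {}
        for (k, tt), j in self.assign.items():
            if tt == t:
                out.setdefault(j, []).append(k)
        for ks in out.values():
            ks.sort()
        return out

    def lifespan(self, j: int) -> tuple[int, int]:
        ts = [t for (_, t), jj in self.assign.items() if jj == j]
        if not ts:
            raise KeyError(f"patch {j} has no points")
        return min(ts), max(ts)

    def copy(self) -> "PatchAssignment":
        return PatchAssignment(
            dict(self.assign), list(self.split_events), list(self.merge_events)
        )


class _TrajIndex:
    """Per-trajectory lookups: frame -> position and color."""

    def __init__(self, trajs: list[ParticleTrajectory]):
        self.by_k: dict[int, ParticleTrajectory] = {tr.k: tr for tr in trajs}
        self.xy: dict[int, dict[int, tuple[float, float]]] = {}
        self.rgb: dict[int, dict[int, tuple[float, float, float]]] = {}
        for tr in trajs:
            if tr.features is None:
                raise ValueError(f"trajectory {tr.k} has no colors attached")
            self.xy[tr.k] = {t: (x, y) for t, x, y in tr.points}
            self.rgb[tr.k] = {
                t: rgb for (t, _, _), rgb in zip(tr.points, tr.features)
            }

    def vector(self, k: int, t: int) -> FeatureVector:
        x, y = self.xy[k][t]
        return FeatureVector(t, x, y, *self.rgb[k][t])

    def t_max(self) -> int:
        return max(tr.t_last for tr in self.by_k.values())


def _fresh_id_counter(used: set[int]):
    src = count(0)

    def next_id() -> int:
        for j in src:
            if j not in used:
                used.add(j)
                return j
        raise RuntimeError("unreachable")

    return next_id


# ---------------------------------------------------------------------------
# pass 1: upstream propagation


def propagate_upstream(
    trajs: list[ParticleTrajectory], final_labels: dict[int, int]
) -> PatchAssignment:
    """Carry final-frame patch IDs back along trajectories.

    ``final_labels`` maps trajectory ID -> find_patches label (>= 1) at the
    final frame. Every point of a trajectory alive at the final frame gets
    that label as its patch ID. Marching backward, a trajectory not yet
    assigned when first encountered receives the smallest unused ID
    (starting from 0), applied to all its points.
    """
    idx = _TrajIndex(trajs)
    t_max = idx.t_max()
    assignment = PatchAssignment()
    used = set(final_labels.values())
    fresh = _fresh_id_counter(used)

    assigned: dict[int, int] = {}
    for k, label in final_labels.items():
        assigned[k] = label
    for t in range(t_max - 1, -1, -1):
        present = [
            (idx.xy[k][t][1], idx.xy[k][t][0], k)
            for k in idx.xy
            if t in idx.xy[k] and k not in assigned
        ]
        for _, _, k in sorted(present):
            assigned[k] = fresh()

    for k, j in assigned.items():
        for t in idx.xy[k]:
            assignment.assign[(k, t)] = j
    return assignment


# ---------------------------------------------------------------------------
# pass 2: backward split


def split_pass(
    assignment: PatchAssignment,
    trajs: list[ParticleTrajectory],
    th: PatchThresholds,
) -> PatchAssignment:
    """Backward intra-patch verification.

    At every frame from the second-to-last down to the first, each patch's
    members are re-clustered with the same decision function used for patch
    finding; members whose own color jumps by at least one color threshold
    between this frame and their next observation are additionally
    separated from the rest (a fluorescence state change). If more than
    one group results, the group nearest the patch's downstream centroid
    keeps the ID and every other group receives a fresh ID at this and all
    earlier frames. A singleton patch cannot split spatially, but its lone
    trajectory's history is still cut at a fluorescence jump — a state
    switch of an isolated track is as much a split as one inside a crowd.
    """
    idx = _TrajIndex(trajs)
    t_max = idx.t_max()
    out = assignment.copy()
    used = set(out.assign.values())
    fresh = _fresh_id_counter(used)

    for t in range(t_max - 1, -1, -1):
        members = out.members_at(t)
        for j in sorted(members):
            ks = members[j]
            if len(ks) < 2:
                k = ks[0]
                if not _jumped(k, t, idx, th):
                    continue
                new_id = fresh()
                out.split_events.append((j, new_id, t))
                for tt in idx.xy[k]:
                    if tt <= t and out.assign.get((k, tt)) == j:
                        out.assign[(k, tt)] = new_id
                continue
            groups, steady_flags = _split_groups(ks, t, idx, th)
            if len(groups) <= 1:
                continue
            anchor = _anchor_group(groups, steady_flags, j, t, out, idx)
            for gi, group in enumerate(groups):
                if gi == anchor:
                    continue
                new_id = fresh()
                out.split_events.append((j, new_id, t))
                for k in group:
                    for tt in idx.xy[k]:
                        if tt <= t and out.assign.get((k, tt)) == j:
                            out.assign[(k, tt)] = new_id
    return out


def _jumped(k: int, t: int, idx: _TrajIndex, th: PatchThresholds) -> bool:
    """Did trajectory k's color jump between t and its next observation?"""
    later = [tt for tt in idx.rgb[k] if tt > t]
    if not later:
        return False
    return not th.colors_similar(idx.rgb[k][t], idx.rgb[k][min(later)])


def _split_groups(ks, t, idx: _TrajIndex, th: PatchThresholds):
    """Partition patch members at frame t: Phi components, jumpers apart.

    Returns the groups and a parallel flag marking the groups made of
    steady (non-jumping) members.
    """
    jumpers, steady = [], []
    for k in ks:
        if _jumped(k, t, idx, th):
            jumpers.append(k)
        else:
            steady.append(k)
    groups: list[list[int]] = []
    steady_flags: list[bool] = []
    for subset, is_steady in ((steady, True), (jumpers, False)):
        if not subset:
            continue
        vecs = [idx.vector(k, t) for k in subset]
        labels = find_patches(vecs, th)
        for lbl in sorted(set(labels)):
            groups.append([k for k, l in zip(subset, labels) if l == lbl])
            steady_flags.append(is_steady)
    return groups, steady_flags


def _anchor_group(
    groups, steady_flags, j, t, assignment: PatchAssignment, idx: _TrajIndex
) -> int:
    """Index of the group that keeps the patch ID.

    Groups whose members' fluorescence jumped never anchor — their history
    diverges from the patch's downstream identity, which stays with the
    steady members (in the worked example the unchanged dark track keeps
    its ID while the switching track's history is split off). Among the
    eligible groups, the one holding the member closest to the patch's
    centroid at t+1 anchors; without downstream members, the group holding
    the minimum (y, x) member. Ties break toward the minimum (y, x).
    """
    downstream = [
        idx.xy[k][t + 1]
        for (k, tt), jj in assignment.assign.items()
        if jj == j and tt == t + 1
    ]
    if downstream:
        cx = float(np.mean([p[0] for p in downstream]))
        cy = float(np.mean([p[1] for p in downstream]))

        def group_key(group):
            best = min(
                (
                    math.hypot(idx.xy[k][t][0] - cx, idx.xy[k][t][1] - cy),
                    idx.xy[k][t][1],
                    idx.xy[k][t][0],
                )
                for k in group
            )
            return best

    else:

        def group_key(group):
            return min((idx.xy[k][t][1], idx.xy[k][t][0]) for k in group)

    eligible = [i for i, st in enumerate(steady_flags) if st] or list(
        range(len(groups))
    )
    keys = {i: group_key(groups[i]) for i in eligible}
    return min(eligible, key=lambda i: keys[i])


# ---------------------------------------------------------------------------
# pass 3: forward merge


def merge_pass(
    assignment: PatchAssignment,
    trajs: list[ParticleTrajectory],
    th: PatchThresholds,
) -> PatchAssignment:
    """Forward inter-patch verification.

    Sweeping from the first frame to the last, coexisting patch pairs whose
    oriented bounding rectangles intersect merge when some cross-pair of
    members satisfies Phi (the absorbed patch is relabeled at this and all
    later frames). A patch starting at this frame also absorbs a patch
    whose lifespan ended at most ``delta_t`` frames earlier when their
    boundary-frame rectangles intersect and their mean colors agree within
    the color thresholds. The patch whose lifespan ends later survives a
    merge; ties break toward the smaller ID.
    """
    idx = _TrajIndex(trajs)
    t_max = idx.t_max()
    out = assignment.copy()

    def current_spans() -> dict[int, tuple[int, int]]:
        spans: dict[int, tuple[int, int]] = {}
        for (_, tt), j in out.assign.items():
            lo, hi = spans.get(j, (tt, tt))
            spans[j] = (min(lo, tt), max(hi, tt))
        return spans

    for t in range(t_max + 1):
        # merge-window case: newly starting patches absorb recently dead ones
        spans = current_spans()
        starters = sorted(j for j, (lo, _) in spans.items() if lo == t)
        for j in starters:
            dead = sorted(
                q
                for q, (_, hi) in spans.items()
                if q != j and hi < t and t - hi <= th.delta_t
            )
            for q in dead:
                if not _window_merge_ok(q, j, t, spans, out, idx, th):
                    continue
                # the absorbed patch is dead at the merge time, so the
                # relabeling covers its whole lifespan
                for key, jj in list(out.assign.items()):
                    if jj == q:
                        out.assign[key] = j
                out.merge_events.append((q, j, t))
                spans = current_spans()

        # coexisting case: iterate until no pair merges at this frame
        while True:
            members = out.members_at(t)
            live = sorted(members)
            merged = False
            spans = current_spans()
            for a_pos in range(len(live)):
                for b_pos in range(a_pos + 1, len(live)):
                    ja, jb = live[a_pos], live[b_pos]
                    if not _contact_merge_ok(
                        members[ja], members[jb], t, idx, th
                    ):
                        continue
                    survivor, absorbed = _survivor(ja, jb, spans)
                    for (k, tt), jj in list(out.assign.items()):
                        if jj == absorbed and tt >= t:
                            out.assign[(k, tt)] = survivor
                    out.merge_events.append((absorbed, survivor, t))
                    merged = True
                    break
                if merged:
                    break
            if not merged:
                break
    return out


def _survivor(ja: int, jb: int, spans) -> tuple[int, int]:
    ha, hb = spans[ja][1], spans[jb][1]
    if ha != hb:
        return (ja, jb) if ha > hb else (jb, ja)
    return (min(ja, jb), max(ja, jb))


def _contact_merge_ok(ks_a, ks_b, t, idx: _TrajIndex, th: PatchThresholds) -> bool:
    pts_a = np.array([idx.xy[k][t] for k in ks_a])
    pts_b = np.array([idx.xy[k][t] for k in ks_b])
    if obb_distance(pts_a, pts_b) >= th.t_d:
        return False
    vecs_a = [idx.vector(k, t) for k in ks_a]
    vecs_b = [idx.vector(k, t) for k in ks_b]
    tree_b = cKDTree(pts_b)
    for va, pa in zip(vecs_a, pts_a):
        for bi in tree_b.query_ball_point(pa, th.t_d):
            if phi(va, vecs_b[bi], th):
                return True
    return False


def _window_merge_ok(q, j, t, spans, assignment, idx, th) -> bool:
    hi_q = spans[q][1]
    members = assignment.members_at(hi_q)
    ks_q = members.get(q, [])
    ks_j = assignment.members_at(t).get(j, [])
    if not ks_q or not ks_j:
        return False
    pts_q = np.array([idx.xy[k][hi_q] for k in ks_q])
    pts_j = np.array([idx.xy[k][t] for k in ks_j])
    if obb_distance(pts_q, pts_j) >= th.t_d:
        return False
    mean_q = _mean_color(q, assignment, idx)
    mean_j = _mean_color(j, assignment, idx)
    return th.colors_similar(mean_q, mean_j)


def _mean_color(j, assignment: PatchAssignment, idx: _TrajIndex):
    cols = [
        idx.rgb[k][t] for (k, t), jj in assignment.assign.items() if jj == j
    ]
    arr = np.array(cols, dtype=float)
    return tuple(arr.mean(axis=0))


# ---------------------------------------------------------------------------
# lineage graph


def build_lineage_graph(
    assignment: PatchAssignment,
    trajs: list[ParticleTrajectory],
    th: PatchThresholds | None = None,
) -> nx.MultiDiGraph:
    """Assemble the patch-lineage DAG from the final assignment.

    One node per surviving patch ID, annotated with its lifespan, point
    count and mean color. Edges come from the final assignment itself:
    whenever a trajectory carries patch ID ``a`` at one observation and
    ``b != a`` at the next, patch ``a`` flows into patch ``b`` at that
    frame, so all edges point forward in time. Two kinds of flow count as
    lineage edges:

    * *terminal flows* — the transition happens after ``a``'s lifespan
      ends (``a`` drained into ``b``); these can never form a cycle,
      because the source's end time strictly increases along any path;
    * *exchange flows* — at least two trajectories move from ``a`` to a
      coexisting patch ``b`` (e.g. a subpopulation emerging out of a
      patch that itself lives on). Single-trajectory exchanges are
      bookkeeping churn and are ignored. Where both directions between two
      patches carry flow, only the dominant direction is kept, and any
      directed cycle still remaining is broken by removing its weakest
      exchange flow (removed flows are recorded in
      ``graph.graph["pruned_flows"]``), so the result is always a DAG.

    Each edge is labeled by what happens to the transitioning
    trajectories' own fluorescence across the transition: if at least half
    of them jump by a color threshold (``th``; 50 intensity units per
    channel when not given), the edge marks a state change and is a
    ``split``; otherwise it is a spatial union, a ``merge``. Merge events
    that left no trace in the final assignment — a patch absorbed over its
    whole lifespan, like a dying track folded into its neighbor — are kept
    in ``graph.graph["absorbed_events"]``.
    """
    idx = _TrajIndex(trajs)
    for tr in trajs:
        for t, _, _ in tr.points:
            if (tr.k, t) not in assignment.assign:
                raise ValueError(f"dangling point: trajectory {tr.k} at frame {t}")

    graph = nx.MultiDiGraph()
    spans: dict[int, tuple[int, int]] = {}
    counts: dict[int, int] = {}
    for (k, t), j in assignment.assign.items():
        lo, hi = spans.get(j, (t, t))
        spans[j] = (min(lo, t), max(hi, t))
        counts[j] = counts.get(j, 0) + 1
    for j, (lo, hi) in sorted(spans.items()):
        mean = _mean_color(j, assignment, idx)
        graph.add_node(
            j,
            t_start=lo,
            t_end=hi,
            n_points=counts[j],
            mean_r=round(mean[0], 3),
            mean_g=round(mean[1], 3),
            mean_b=round(mean[2], 3),
        )

    # patch-ID transitions along trajectories define the edges
    transitions: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for tr in trajs:
        for (t1, _, _), (t2, _, _) in zip(tr.points, tr.points[1:]):
            a = assignment.assign[(tr.k, t1)]
            b = assignment.assign[(tr.k, t2)]
            if a != b:
                transitions.setdefault((a, b), []).append((t1, t2, tr.k))

    color_th = (50.0, 50.0, 50.0) if th is None else (th.t_r, th.t_g, th.t_b)

    def jumped(k: int, t1: int, t2: int) -> bool:
        c1, c2 = idx.rgb[k][t1], idx.rgb[k][t2]
        return any(abs(x - y) >= lim for x, y, lim in zip(c1, c2, color_th))

    flows: dict[tuple[int, int], dict] = {}
    for (a, b), moves in transitions.items():
        times = [t2 for _, t2, _ in moves]
        terminal = min(times) > spans[a][1]
        if terminal or len(moves) >= 2:
            n_jump = sum(jumped(k, t1, t2) for t1, t2, k in moves)
            flows[(a, b)] = dict(
                t=min(times),
                n=len(moves),
                terminal=terminal,
                kind="split" if 2 * n_jump >= len(moves) else "merge",
            )

    # keep only the dominant direction between any two patches
    for a, b in sorted(flows):
        if (b, a) not in flows or (a, b) not in flows:
            continue
        fab, fba = flows[(a, b)], flows[(b, a)]

        def rank(flow, src):
            return (flow["terminal"], flow["n"], -flow["t"], -src)

        loser = (b, a) if rank(fab, a) >= rank(fba, b) else (a, b)
        del flows[loser]

    for (a, b), flow in sorted(flows.items()):
        graph.add_edge(
            a, b, type=flow["kind"], t=flow["t"], n_trajectories=flow["n"],
            terminal=flow["terminal"],
        )

    # exchange flows can in principle still close a directed cycle through
    # several patches; break each by dropping its weakest exchange flow
    pruned: list[dict] = []
    while not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        exchange = [
            (u, v, key)
            for u, v, key in cycle
            if not graph.edges[u, v, key]["terminal"]
        ]
        if not exchange:  # cannot happen: terminal-only cycles are impossible
            raise ValueError("patch lineage contains a terminal-flow cycle")
        u, v, key = min(
            exchange,
            key=lambda e: (
                graph.edges[e]["n_trajectories"],
                -graph.edges[e]["t"],
                -e[0],
                -e[1],
            ),
        )
        pruned.append(dict(source=u, target=v, **graph.edges[u, v, key]))
        graph.remove_edge(u, v, key)
    graph.graph["pruned_flows"] = pruned

    # events invisible in the final assignment (fully absorbed patches)
    absorbed_events = [
        dict(type="merge", source=a, target=b, t=t)
        for a, b, t in assignment.merge_events
        if a not in graph.nodes
    ]
    graph.graph["absorbed_events"] = absorbed_events
    return graph


def final_patches(graph: nx.MultiDiGraph) -> list[int]:
    """Nodes whose lifespan reaches the last frame of the movie."""
    t_max = max(a["t_end"] for _, a in graph.nodes(data=True))
    return sorted(n for n, a in graph.nodes(data=True) if a["t_end"] == t_max)


def lineage_families(graph: nx.MultiDiGraph) -> dict[int, set[int]]:
    """Ancestor closure of every final patch: its whole lineage family.

    A trajectory whose track dies mid-movie lives in an upstream patch
    that flows into a colony patch through a merge edge; the family of a
    final patch is itself plus all nodes with a directed path into it.
    """
    return {n: nx.ancestors(graph, n) | {n} for n in final_patches(graph)}


def family_point_coverage(graph: nx.MultiDiGraph) -> float:
    """Fraction of all trajectory points covered by the lineage families."""
    total = sum(a["n_points"] for _, a in graph.nodes(data=True))
    covered_nodes = set().union(*lineage_families(graph).values())
    covered = sum(
        a["n_points"] for n, a in graph.nodes(data=True) if n in covered_nodes
    )
    return covered / total if total else 0.0


@dataclass
class PatchLineageResult:
    """Everything the lineage computation produces.

    ``pre_merge`` is the assignment after the upstream and split passes
    but before merging; unlike the final assignment it contains no
    whole-lifespan relabels, which makes it the right basis for
    attributing patches to ground-truth populations in analyses.
    """

    assignment: PatchAssignment
    graph: nx.MultiDiGraph
    final_labels: dict[int, int]
    thresholds: PatchThresholds
    pre_merge: PatchAssignment | None = None

    def patch_boundaries(self, trajs: list[ParticleTrajectory], t: int, alpha=None):
        """Concave-hull boundary loops per patch at frame t."""
        alpha = self.thresholds.t_d if alpha is None else alpha
        idx = _TrajIndex(trajs)
        out = {}
        for j, ks in self.assignment.members_at(t).items():
            out[j] = concave_hull([idx.xy[k][t] for k in ks], alpha)
        return out


def compute_patch_lineage(
    trajs: list[ParticleTrajectory], th: PatchThresholds
) -> PatchLineageResult:
    """Run patch finding at the final frame plus the three passes."""
    if not trajs:
        raise ValueError("no trajectories")
    idx = _TrajIndex(trajs)
    t_max = idx.t_max()
    alive = sorted(k for k in idx.xy if t_max in idx.xy[k])
    vecs = [idx.vector(k, t_max) for k in alive]
    labels = find_patches(vecs, th)
    final_labels = {k: int(lbl) for k, lbl in zip(alive, labels)}
    assignment = propagate_upstream(trajs, final_labels)
    assignment = split_pass(assignment, trajs, th)
    pre_merge = assignment.copy()
    assignment = merge_pass(assignment, trajs, th)
    graph = build_lineage_graph(assignment, trajs, th)
    return PatchLineageResult(assignment, graph, final_labels, th, pre_merge)


# ---------------------------------------------------------------------------
# worked example


def six_track_example() -> tuple[list[ParticleTrajectory], PatchThresholds]:
    """Six-trajectory schematic exercising every lineage event.

    Six parallel tracks on rows y = 10..60 px, x = 10 t, over 8 frames.
    Track 2 exists only for t = 0..4 (it receives the fresh ID 0 and is
    later absorbed into its gray neighbor); track 5 is gray until t = 6 and
    switches dark at t = 7, so the backward pass splits its history off as
    a new patch. With thresholds t_d = 15 and 50 per channel, adjacent rows
    pass the distance test and non-adjacent rows fail it; initial patch
    finding at the final frame yields 4 patches and the completed pipeline
    yields 5.
    """
    white = (230.0, 230.0, 230.0)
    gray = (128.0, 128.0, 128.0)
    dark = (60.0, 60.0, 60.0)

    def color_of(row: int, t: int):
        if row == 1 or row == 6:
            return white
        if row == 4:
            return dark
        if row == 5:
            return dark if t == 7 else gray
        return gray  # rows 2 and 3

    trajs = []
    for row in range(1, 7):
        frames = range(0, 5) if row == 2 else range(0, 8)
        points = [(t, 10.0 * t, 10.0 * row) for t in frames]
        feats = [color_of(row, t) for t in frames]
        trajs.append(ParticleTrajectory(k=row, points=points, features=feats))
    return trajs, PatchThresholds(t_d=15.0, t_r=50.0, t_g=50.0, t_b=50.0, delta_t=3)
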