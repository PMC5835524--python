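"""Concave hulls and oriented-bounding-rectangle overlap tests.

Patch boundaries are concave hulls (alpha-shape flavor): Delaunay
triangulate the member positions, drop triangles with any edge longer than
``alpha``, and read the boundary off the edges that belong to exactly one
remaining triangle. The merge pass pre-screens patch pairs with a
minimum-area oriented bounding rectangle intersection test, which is
conservative: it can report overlap for disjoint point sets but never
misses a true intersection.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint

__all__ = ["concave_hull", "oriented_bounding_box", "obb_overlap"]


def concave_hull(points, alpha: float) -> list[np.ndarray]:
    """Boundary loops of the alpha-shape of ``points``.

    Parameters
    ----------
    points:
        (n, 2) array-like of (x, y) positions, n >= 1.
    alpha:
        Longest triangle edge kept, in px.

    Returns
    -------
    list of (m, 2) arrays, each an ordered closed loop of boundary points.
    Degenerate inputs (fewer than 3 points, collinear points, or no
    triangle surviving the edge cut) return the input points as one "loop".
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if pts.shape[0] < 3:
        return [pts.copy()]
    try:
        tri = Delaunay(pts)
    except QhullError:  # collinear or otherwise degenerate
        return [pts.copy()]

    def edge_ok(i, j):
        return np.hypot(*(pts[i] - pts[j])) <= alpha

    kept = [
        simplex
        for simplex in tri.simplices
        if edge_ok(simplex[0], simplex[1])
        and edge_ok(simplex[1], simplex[2])
        and edge_ok(simplex[0], simplex[2])
    ]
    if not kept:
        return [pts.copy()]

    edge_count: dict[tuple[int, int], int] = {}
    for a, b, c in kept:
        for i, j in ((a, b), (b, c), (a, c)):
            key = (min(i, j), max(i, j))
            edge_count[key] = edge_count.get(key, 0) + 1
    boundary = [e for e, n in edge_count.items() if n == 1]
    if not boundary:
        return [pts.copy()]

    adj: dict[int, list[int]] = {}
    for i, j in boundary:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    loops: list[np.ndarray] = []
    unused = {tuple(sorted(e)) for e in boundary}
    while unused:
        start = min(unused)[0]
        loop = [start]
        prev, cur = None, start
        while True:
            nxts = [n for n in sorted(adj[cur]) if n != prev and
                    (min(cur, n), max(cur, n)) in unused]
            if not nxts:
                break
            nxt = nxts[0]
            unused.discard((min(cur, nxt), max(cur, nxt)))
            if nxt == start:
                break
            loop.append(nxt)
            prev, cur = cur, nxt
        loops.append(pts[loop])
    return loops


def oriented_bounding_box(points):
    """Minimum-area oriented bounding rectangle as a shapely geometry.

    Degenerate inputs yield a point or segment, which still participate in
    intersection tests.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    return MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle


def obb_overlap(points_a, points_b) -> bool:
    """Do the oriented bounding rectangles of two point sets intersect?

    Touching counts as overlap; the test is conservative with respect to
    the underlying hulls (never False when the hulls truly intersect).
    """
    return bool(oriented_bounding_box(points_a).intersects(oriented_bounding_box(points_b)))


def obb_distance(points_a, points_b) -> float:
    """Distance between the oriented bounding rectangles of two point sets.

    0 when the rectangles intersect. ``obb_distance(a, b) < t_d`` is the
    merge-pass pre-screen: it is conservative for the decision function
    (some cross pair within ``t_d`` implies rectangle distance below
    ``t_d``) and, unlike a bare intersection test, stays meaningful for
    single-particle patches whose rectangles are degenerate points.
    """
    return float(
        oriented_bounding_box(points_a).distance(oriented_bounding_box(points_b))
    )


def hull_diameter(points) -> float:
    """Largest pairwise distance; cheap O(n^2), used for summaries only."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        return 0.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return math.sqrt(float(d2.max()))
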