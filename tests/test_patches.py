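"""Decision function, patch finding, propagation passes, worked example."""

import numpy as np
import pytest

from patchtrace import (
    FeatureVector,
    ParticleTrajectory,
    PatchThresholds,
    build_lineage_graph,
    compute_patch_lineage,
    find_patches,
    phi,
    propagate_upstream,
    six_track_example,
)

TH = PatchThresholds(t_d=15.0, t_r=50.0, t_g=50.0, t_b=50.0, delta_t=3)


def vec(x, y, r=100.0, g=100.0, b=100.0, t=0):
    return FeatureVector(t, x, y, r, g, b)


class TestPhi:
    def test_identical_vectors_match(self):
        v = vec(1, 2)
        assert phi(v, v, TH) == 1

    def test_distance_threshold_is_strict(self):
        assert phi(vec(0, 0), vec(15.0, 0), TH) == 0  # exactly t_d
        assert phi(vec(0, 0), vec(14.999, 0), TH) == 1

    @pytest.mark.parametrize("channel", ["r", "g", "b"])
    def test_one_failing_channel_vetoes_the_product(self, channel):
        kwargs = {channel: 160.0}  # difference 60 >= 50
        assert phi(vec(0, 0), vec(1, 1, **kwargs), TH) == 0


def brute_force_labels(points, th):
    """Independent oracle: union-find over the explicit pairwise Phi matrix."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if phi(points[i], points[j], th):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values()}


def random_frame(rng, n):
    return [
        vec(rng.uniform(0, 120), rng.uniform(0, 120),
            rng.uniform(0, 255), rng.uniform(0, 255), rng.uniform(0, 255))
        for _ in range(n)
    ]


class TestFindPatches:
    def test_empty_input(self):
        assert find_patches([], TH).size == 0

    def test_mutually_dissimilar_points_stay_separate(self):
        pts = [vec(0, 0), vec(50, 0), vec(0, 50)]
        assert len(set(find_patches(pts, TH))) == 3

    def test_transitive_chaining(self):
        a, b, c = vec(0, 0), vec(10, 0), vec(20, 0)  # a-c distance 20 >= t_d
        labels = find_patches([a, b, c], TH)
        assert len(set(labels)) == 1

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            pts = random_frame(rng, int(rng.integers(0, 80)))
            labels = find_patches(pts, TH)
            got = {
                frozenset(i for i, l in enumerate(labels) if l == lbl)
                for lbl in set(labels)
            }
            assert got == brute_force_labels(pts, TH)

    def test_looser_thresholds_never_increase_patch_count(self):
        rng = np.random.default_rng(8)
        pts = random_frame(rng, 60)
        tight = PatchThresholds(t_d=12.0, t_r=40.0, t_g=40.0, t_b=40.0)
        for loose in (
            PatchThresholds(t_d=20.0, t_r=40.0, t_g=40.0, t_b=40.0),
            PatchThresholds(t_d=12.0, t_r=90.0, t_g=40.0, t_b=40.0),
            PatchThresholds(t_d=25.0, t_r=90.0, t_g=90.0, t_b=90.0),
        ):
            assert len(set(find_patches(pts, loose))) <= len(set(find_patches(pts, tight)))

    def test_labels_are_deterministic_and_one_based(self):
        pts = [vec(0, 30), vec(0, 0)]  # separate patches; top-left first
        labels = find_patches(pts, TH)
        assert labels.tolist() == [2, 1]


class TestWorkedExample:
    """The six-track schematic reproduces every narrated lineage event."""

    def test_initial_patch_finding_at_the_final_frame(self):
        trajs, th = six_track_example()
        alive = [tr for tr in trajs if tr.t_last == 7]
        assert len(trajs) == 6 and len(alive) == 5
        vecs = [tr.feature_vectors()[-1] for tr in alive]
        labels = find_patches(vecs, th)
        assert len(set(labels)) == 4
        sizes = sorted(np.bincount(labels)[1:].tolist())
        assert sizes == [1, 1, 1, 2]
        # the two-member patch holds the dark tracks on rows 4 and 5
        big = max(set(labels), key=lambda l: (labels == l).sum())
        assert {alive[i].k for i in range(5) if labels[i] == big} == {4, 5}

    def test_absent_track_receives_fresh_id_zero(self):
        trajs, th = six_track_example()
        alive = {tr.k: tr for tr in trajs if tr.t_last == 7}
        vecs = [alive[k].feature_vectors()[-1] for k in sorted(alive)]
        labels = find_patches(vecs, th)
        assignment = propagate_upstream(trajs, dict(zip(sorted(alive), map(int, labels))))
        assert assignment.assign[(2, 0)] == 0
        assert all(assignment.assign[(2, t)] == 0 for t in range(5))

    def test_split_creates_patch_five_at_the_second_to_last_frame(self):
        res = compute_patch_lineage(*six_track_example())
        assert (3, 5, 6) in res.assignment.split_events
        assert all(res.assignment.assign[(5, t)] == 5 for t in range(7))
        assert res.assignment.assign[(5, 7)] == 3

    def test_merge_absorbs_patch_zero_into_patch_two(self):
        res = compute_patch_lineage(*six_track_example())
        assert (0, 2, 0) in res.assignment.merge_events
        assert all(res.assignment.assign[(2, t)] == 2 for t in range(5))

    def test_final_graph_has_five_patches_and_the_split_edge(self):
        res = compute_patch_lineage(*six_track_example())
        assert sorted(res.graph.nodes) == [1, 2, 3, 4, 5]
        edges = [(u, v, a["type"], a["t"]) for u, v, a in res.graph.edges(data=True)]
        assert (5, 3, "split", 7) in edges


def constant_traj(k, y, frames, color=(128.0, 128.0, 128.0), x0=0.0, dx=0.0):
    points = [(t, x0 + dx * t, y) for t in frames]
    return ParticleTrajectory(k, points, [color] * len(points))


class TestSplitPass:
    def test_homogeneous_patch_is_untouched(self):
        trajs = [constant_traj(0, 0.0, range(8)), constant_traj(1, 5.0, range(8))]
        res = compute_patch_lineage(trajs, TH)
        assert not res.assignment.split_events

    def test_two_clusters_split_exactly_where_they_separate(self):
        # clusters 2*t_d apart for t = 0..5, joined at t = 6..9
        def pos(base, t):
            return base if t >= 6 else base + 30.0 * (1 if base > 0 else -1)

        trajs = []
        for k, base in enumerate((-5.0, 5.0)):
            pts = [(t, pos(base, t), 0.0) for t in range(10)]
            trajs.append(ParticleTrajectory(k, pts, [(128.0,) * 3] * 10))
        res = compute_patch_lineage(trajs, TH)
        assert [t for _, _, t in res.assignment.split_events] == [5]

    def test_singleton_track_splits_at_a_fluorescence_jump(self):
        pts = [(t, 0.0, 0.0) for t in range(8)]
        colors = [(230.0,) * 3 if t >= 5 else (60.0,) * 3 for t in range(8)]
        trajs = [ParticleTrajectory(0, pts, colors)]
        res = compute_patch_lineage(trajs, TH)
        assert [t for _, _, t in res.assignment.split_events] == [4]


class TestLineageGraph:
    def test_single_trajectory_gives_one_node_no_edges(self):
        res = compute_patch_lineage([constant_traj(0, 0.0, range(6))], TH)
        assert res.graph.number_of_nodes() == 1
        assert res.graph.number_of_edges() == 0

    def test_dangling_points_are_rejected(self):
        trajs = [constant_traj(0, 0.0, range(4))]
        res = compute_patch_lineage(trajs, TH)
        extra = constant_traj(9, 50.0, range(4))
        with pytest.raises(ValueError, match="dangling"):
            build_lineage_graph(res.assignment, trajs + [extra])

    def test_node_count_never_exceeds_trajectory_count(self):
        rng = np.random.default_rng(5)
        trajs = []
        for k in range(12):
            t0 = int(rng.integers(0, 4))
            span = int(rng.integers(2, 8))
            frames = range(t0, min(10, t0 + span))
            color = tuple(rng.uniform(0, 255, 3))
            trajs.append(constant_traj(k, float(rng.uniform(0, 80)), frames, color))
        res = compute_patch_lineage(trajs, PatchThresholds(t_d=25.0))
        assert res.graph.number_of_nodes() <= len(trajs)
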