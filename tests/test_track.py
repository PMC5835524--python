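"""Trajectory linking against an exhaustive oracle, filtering, colors."""

import itertools
import math

import numpy as np
import pytest

from patchtrace import (
    Frame,
    LinkingParams,
    ParticleTrajectory,
    attach_colors,
    default_linking_params,
    filter_trajectories,
    link_particles,
)
from patchtrace.detect import Particle


def as_particles(frames_xy):
    """[[(x, y), ...] per frame] -> per-frame Particle lists."""
    out = []
    for t, pts in enumerate(frames_xy):
        out.append([Particle(t=t, p=i, x=x, y=y, mass=1.0) for i, (x, y) in enumerate(pts)])
    return out


# ---------------------------------------------------------------------------
# oracle: frame-by-frame exhaustive assignment, minimum total squared
# displacement with an unfilled-link cost of sigma_max**2 (no memory)


def oracle_link(frames_xy, sigma_max):
    tracks = []  # list of lists of (t, x, y); last point at previous frame = open
    for t, pts in enumerate(frames_xy):
        open_idx = [i for i, tr in enumerate(tracks) if tr[-1][0] == t - 1]
        best = None
        for assignment in _enumerate_assignments(open_idx, len(pts)):
            cost = 0.0
            feasible = True
            linked_tracks = set(assignment)
            for ti, pi in assignment.items():
                _, x0, y0 = tracks[ti][-1]
                d2 = (pts[pi][0] - x0) ** 2 + (pts[pi][1] - y0) ** 2
                if d2 > sigma_max**2:
                    feasible = False
                    break
                cost += d2
            if not feasible:
                continue
            cost += sigma_max**2 * (len(open_idx) - len(linked_tracks))
            cost += sigma_max**2 * (len(pts) - len(linked_tracks))
            if best is None or cost < best[0]:
                best = (cost, assignment)
        assignment = best[1] if best else {}
        taken = set(assignment.values())
        for ti, pi in assignment.items():
            tracks[ti].append((t, *pts[pi]))
        for pi, (x, y) in enumerate(pts):
            if pi not in taken:
                tracks.append([(t, x, y)])
    return {tuple(tr) for tr in tracks}


def _enumerate_assignments(track_ids, n_pts):
    for r in range(min(len(track_ids), n_pts) + 1):
        for subset in itertools.combinations(track_ids, r):
            for perm in itertools.permutations(range(n_pts), r):
                yield dict(zip(subset, perm))


def random_walk_instance(rng, sigma_max, n_frames=5, max_particles=4):
    walkers = []
    n = rng.integers(1, max_particles + 1)
    for _ in range(n):
        x, y = rng.uniform(10, 90, 2)
        walkers.append([(float(x), float(y))])
    for _ in range(n_frames - 1):
        for w in walkers:
            ang = rng.uniform(0, 2 * math.pi)
            step = rng.uniform(0, sigma_max / 2)
            x, y = w[-1]
            w.append((x + step * math.cos(ang), y + step * math.sin(ang)))
    return [[w[t] for w in walkers] for t in range(n_frames)]


def test_linking_matches_the_exhaustive_oracle():
    sigma = 6.0
    params = LinkingParams(sigma_max=sigma, W_max=0, W_min=1)
    rng = np.random.default_rng(42)
    for _ in range(40):
        frames_xy = random_walk_instance(rng, sigma)
        got = {tuple(tr.points) for tr in link_particles(as_particles(frames_xy), params)}
        assert got == oracle_link(frames_xy, sigma)


def test_stationary_particles_give_two_full_tracks():
    frames_xy = [[(20.0, 20.0), (80.0, 80.0)] for _ in range(10)]
    trajs = link_particles(as_particles(frames_xy), LinkingParams(6.0, 0, 1))
    assert len(trajs) == 2
    assert all(len(tr.points) == 10 for tr in trajs)


def test_memory_bridges_a_gap_of_w_max_frames():
    w_max = 3
    frames_xy = [[(50.0, 50.0)], [(51.0, 50.0)]] + [[]] * w_max + [[(52.0, 50.0)]]
    trajs = link_particles(as_particles(frames_xy), LinkingParams(5.0, w_max, 1))
    assert len(trajs) == 1
    assert [t for t, _, _ in trajs[0].points] == [0, 1, 1 + w_max + 1]
    # one frame longer and the track is cut
    frames_xy = [[(50.0, 50.0)]] + [[]] * (w_max + 1) + [[(50.0, 50.0)]]
    trajs = link_particles(as_particles(frames_xy), LinkingParams(5.0, w_max, 1))
    assert len(trajs) == 2


def test_points_belong_to_exactly_one_trajectory():
    rng = np.random.default_rng(3)
    frames_xy = [
        [tuple(rng.uniform(0, 100, 2)) for _ in range(rng.integers(0, 8))]
        for _ in range(12)
    ]
    trajs = link_particles(as_particles(frames_xy), LinkingParams(10.0, 2, 1))
    seen = [pt for tr in trajs for pt in tr.points]
    assert len(seen) == len(set(seen)) == sum(len(f) for f in frames_xy)


@pytest.mark.parametrize(
    "d,frames,expected",
    [(11, 100, (9.0, 15, 10)), (9, 115, (7.0, 17, 11)), (3, 1, (1.0, 0, 1))],
)
def test_default_linking_params(d, frames, expected):
    p = default_linking_params(d, frames)
    assert (p.sigma_max, p.W_max, p.W_min) == expected


def test_span_filter():
    def traj(k, t0, t1):
        return ParticleTrajectory(k, [(t, 0.0, 0.0) for t in range(t0, t1 + 1)])

    trajs = [traj(0, 0, 1), traj(1, 3, 13), traj(2, 5, 8)]  # spans 2, 11, 4
    assert [tr.k for tr in filter_trajectories(trajs, 10)] == [1]
    assert filter_trajectories(trajs, 1) == trajs
    counts = [len(filter_trajectories(trajs, w)) for w in range(1, 14)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def make_frames(arrs):
    return [Frame(t, {c: a[..., i] for i, c in enumerate("rgb")}) for t, a in enumerate(arrs)]


def test_color_normalization_maps_the_midpoint():
    a = np.zeros((20, 20, 3))
    a[..., :] = 10.0
    a[5, 5, :] = 60.0
    a[7, 7, :] = 110.0  # global max
    trajs = [ParticleTrajectory(0, [(0, 5.0, 5.0)])]
    out = attach_colors(trajs, make_frames([a]))
    assert out[0].features[0] == pytest.approx((127.5, 127.5, 127.5))


def test_black_particles_are_dropped():
    a = np.zeros((20, 20, 3))
    a[3, 3, :] = 200.0
    trajs = [
        ParticleTrajectory(0, [(0, 10.0, 10.0)]),  # samples the global minimum
        ParticleTrajectory(1, [(0, 3.0, 3.0)]),
    ]
    out = attach_colors(trajs, make_frames([a]))
    assert [tr.k for tr in out] == [1]


def test_trajectory_colors_separate_two_populations():
    rng = np.random.default_rng(0)
    arrs = []
    for _ in range(4):
        a = rng.normal(5, 2, (60, 60, 3)).clip(0, 255)
        a[10:30, 10:30, 0] += 200  # red block
        a[35:55, 35:55, 1] += 200  # green block
        arrs.append(a.clip(0, 255))
    trajs = [
        ParticleTrajectory(0, [(t, 20.0, 20.0) for t in range(4)]),
        ParticleTrajectory(1, [(t, 22.0, 18.0) for t in range(4)]),
        ParticleTrajectory(2, [(t, 45.0, 45.0) for t in range(4)]),
        ParticleTrajectory(3, [(t, 47.0, 44.0) for t in range(4)]),
    ]
    out = attach_colors(trajs, make_frames(arrs))
    means = {tr.k: np.mean(tr.features, axis=0) for tr in out}
    assert means[0][0] > 150 and means[1][0] > 150
    assert means[2][1] > 150 and means[3][1] > 150
    assert means[0][1] < 60 and means[2][0] < 60
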