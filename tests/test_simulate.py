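"""Simulator mechanics: growth, division, relaxation, rendering, bookkeeping."""

import math
from dataclasses import replace

import numpy as np
import pytest

from patchtrace import SimCell, SimConfig, relax_positions, render_frame, simulate_movie
from patchtrace.simulate import _worst_overlap_fraction, step_growth


def make_cell(x=100.0, y=100.0, length=24.0, width=11.0, orient=0.0, cid=0):
    return SimCell(
        id=cid,
        parent_id=None,
        center=(x, y),
        length=length,
        width=width,
        orientation=orient,
        fluor_state="red",
        rgb=(210.0, 40.0, 40.0),
    )


def test_no_growth_is_identity():
    cfg = SimConfig(growth_rate=0.0)
    rng = np.random.default_rng(0)
    cells = [make_cell()]
    for _ in range(10):
        cells, divisions, switches = step_growth(cells, cfg, rng)
        assert not divisions and not switches
    assert len(cells) == 1
    assert cells[0].length == 24.0


def test_first_division_frame_matches_exponential_growth():
    # 10 * 1.26**t >= 20 first at t = 3
    cfg = SimConfig(growth_rate=0.26, division_length=20.0, orientation_jitter=0.0,
                    division_asymmetry=0.0)
    rng = np.random.default_rng(0)
    cells = [make_cell(length=10.0, width=8.0)]
    for t in range(1, 5):
        cells, divisions, _ = step_growth(cells, cfg, rng)
        if divisions:
            assert t == 3
            break
    else:
        pytest.fail("no division occurred")


def test_population_doubles_on_schedule():
    # one doubling per 5 frames from a founder at half the division length:
    # after 20 frames the count should be 2**4 within 20% (symmetric division
    # keeps the calibration exact; crowding must not block divisions)
    cfg = SimConfig(
        frame_count=21,
        image_size=(420, 420),
        initial_cells=1,
        founder_positions=((210.0, 210.0),),
        initial_length=22.0,
        division_asymmetry=0.0,
        seed=5,
    )
    _, gt = simulate_movie(cfg)
    count = len(gt.cells_at(20))
    assert 16 * 0.8 <= count <= 16 * 1.2


def test_division_conserves_length_and_counts():
    cfg = SimConfig(frame_count=15, initial_cells=1,
                    founder_positions=((150.0, 150.0),), seed=3)
    _, gt = simulate_movie(cfg)
    counts = [len(c) for c in gt.snapshots]
    assert all(a <= b for a, b in zip(counts, counts[1:]))
    by_frame = {t: {c.id: c for c in cells} for t, cells in enumerate(gt.snapshots)}
    for t, parent, c1, c2 in gt.divisions:
        kids = by_frame[t]
        grown_parent = by_frame[t - 1][parent].length * (1 + cfg.growth_rate)
        total = kids[c1].length + kids[c2].length
        assert total == pytest.approx(grown_parent, rel=0.01)


def test_relaxation_leaves_disjoint_cells_alone():
    cfg = SimConfig()
    cells = [make_cell(x=50), make_cell(x=200, cid=1)]
    out = relax_positions(cells, cfg)
    assert out[0].center == cells[0].center
    assert out[1].center == cells[1].center


def test_relaxation_pushes_overlapping_pair_apart():
    cfg = SimConfig()
    cells = [make_cell(x=100), make_cell(x=112, cid=1)]  # 0.5 * length apart
    pre = abs(cells[1].center[0] - cells[0].center[0])
    out = relax_positions(cells, cfg)
    post = math.dist(out[0].center, out[1].center)
    assert post >= pre
    assert _worst_overlap_fraction(out) <= cfg.max_overlap_frac


def test_colony_overlap_invariant(small_movie):
    cfg, _, gt = small_movie
    assert _worst_overlap_fraction(gt.cells_at(cfg.frame_count - 1)) <= cfg.max_overlap_frac


def test_render_empty_is_black():
    cfg = SimConfig(noise_sigma=0.0, image_size=(64, 64))
    assert render_frame([], cfg).sum() == 0


def test_render_center_is_brightest_and_boundary_is_half():
    cfg = SimConfig(noise_sigma=0.0, image_size=(200, 200), sigmoid_steepness=10.0)
    cell = make_cell(x=100.0, y=100.0, length=40.0, width=16.0, orient=0.0)
    img = render_frame([cell], cfg)
    red = img[..., 0].astype(float)
    assert red[100, 100] == red.max()
    # boundary pixel (120, 100) sits at rho = 1: half the plateau within 2%
    assert red[100, 120] == pytest.approx(0.5 * red[100, 100], rel=0.02)


def test_render_is_order_independent():
    cfg = SimConfig(noise_sigma=0.0, image_size=(150, 150))
    cells = [make_cell(x=60, cid=0), make_cell(x=90, y=80, cid=1, orient=1.0)]
    a = render_frame(cells, cfg)
    b = render_frame(cells[::-1], cfg)
    assert np.array_equal(a, b)


def test_same_seed_reproduces_frames_bit_exactly():
    cfg = SimConfig(frame_count=6, image_size=(160, 160), seed=11)
    frames_a, _ = simulate_movie(cfg)
    frames_b, _ = simulate_movie(cfg)
    for fa, fb in zip(frames_a, frames_b):
        for c in ("r", "g", "b"):
            assert np.array_equal(fa.channels[c], fb.channels[c])


def test_seed_changes_division_times():
    base = SimConfig(frame_count=25, image_size=(420, 420), initial_cells=1,
                     founder_positions=((210.0, 210.0),))
    _, gt_a = simulate_movie(replace(base, seed=1))
    _, gt_b = simulate_movie(replace(base, seed=2))
    assert gt_a.divisions != gt_b.divisions
    for gt in (gt_a, gt_b):
        counts = [len(c) for c in gt.snapshots]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_two_founders_give_two_families_with_stable_states(small_movie):
    cfg = SimConfig(frame_count=10, image_size=(340, 340), initial_cells=2,
                    founder_positions=((100.0, 170.0), (240.0, 170.0)),
                    founder_states=("red", "green"), seed=2)
    _, gt = simulate_movie(cfg)
    assert gt.n_families() == 2
    for cells in gt.snapshots:  # no switching configured
        for c in cells:
            founder_state = "red" if gt.founder_of(c.id) == 0 else "green"
            assert c.fluor_state == founder_state


def test_programmed_switch_hits_descendants():
    cfg = SimConfig(frame_count=14, image_size=(300, 300), initial_cells=1,
                    founder_positions=((150.0, 150.0),),
                    programmed_switches=((8, 0, "green"),), seed=4)
    _, gt = simulate_movie(cfg)
    assert all(c.fluor_state == "red" for c in gt.cells_at(7))
    assert all(c.fluor_state == "green" for c in gt.cells_at(8))
    assert {t for t, *_ in gt.switches} == {8}


def test_tiny_image_is_rejected():
    with pytest.raises(ValueError):
        simulate_movie(SimConfig(image_size=(20, 20)))
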