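"""Alignment and binarization behavior on constructed and simulated frames."""

import numpy as np

from patchtrace import Frame, align_frames, binarize_frame, preprocess_movie
from patchtrace.frames import translate_image

from conftest import rho_map


def gray_frame(arr, t=0):
    arr = np.asarray(arr)
    return Frame(t, {"r": arr, "g": arr, "b": arr})


def test_identical_frames_align_with_zero_offsets():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, (80, 80))
    frames = [gray_frame(img, t) for t in range(4)]
    _, offsets = align_frames(frames)
    assert offsets == [(0, 0)] * 4


def test_constructed_shift_is_recovered():
    rng = np.random.default_rng(1)
    img = np.zeros((100, 100))
    img[30:60, 20:55] = rng.uniform(100, 200, (30, 35))
    shifted = translate_image(img, 3, -2)
    aligned, offsets = align_frames([gray_frame(img, 0), gray_frame(shifted, 1)])
    assert offsets == [(0, 0), (3, -2)]
    # the aligned frame matches the original away from the border
    diff = np.abs(aligned[1].channels["r"][10:90, 10:90] - img[10:90, 10:90])
    assert diff.max() == 0


def test_noise_frames_stay_within_the_shift_clamp():
    rng = np.random.default_rng(2)
    frames = [gray_frame(rng.uniform(0, 255, (60, 60)), t) for t in range(5)]
    _, offsets = align_frames(frames, max_shift=4)
    assert all(abs(dx) <= 4 and abs(dy) <= 4 for dx, dy in offsets)


def test_constant_frame_gives_empty_mask():
    mask = binarize_frame(gray_frame(np.zeros((50, 50))))
    assert not mask.mask.any()


def test_bright_square_is_recovered_within_one_pixel():
    rng = np.random.default_rng(3)
    img = rng.normal(10, 3, (90, 90))
    img[30:60, 40:70] += 180
    mask = binarize_frame(gray_frame(np.clip(img, 0, 255)))
    truth = np.zeros((90, 90), bool)
    truth[30:60, 40:70] = True
    from scipy.ndimage import binary_dilation

    band = binary_dilation(truth, iterations=1)
    inner = binary_dilation(~truth, iterations=1)
    assert mask.mask[truth & ~inner].all()  # interior fully covered
    assert not mask.mask[~band].any()  # nothing outside a 1-px band


def test_mask_matches_simulated_cell_geometry(clean_movie):
    cfg, frames, gt = clean_movie
    t = cfg.frame_count - 1
    mask = binarize_frame(frames[t]).mask
    rhos = np.stack([rho_map(c, mask.shape) for c in gt.cells_at(t)])
    near = rhos.min(axis=0) <= 0.8
    far = rhos.min(axis=0) >= 1.5
    assert mask[near].mean() >= 0.90
    assert mask[far].mean() <= 0.01


def test_binarization_is_idempotent(clean_movie):
    _, frames, _ = clean_movie
    mask = binarize_frame(frames[-1]).mask
    binary = (mask * 255).astype(np.uint8)
    again = binarize_frame(gray_frame(binary)).mask
    assert np.array_equal(mask, again)


def test_mask_is_invariant_under_affine_intensity_rescale():
    img = np.zeros((60, 60))
    img[20:40, 20:40] = 100.0
    base = binarize_frame(gray_frame(img)).mask
    scaled = binarize_frame(gray_frame(0.4 * img + 17.0)).mask
    assert np.array_equal(base, scaled)


def test_single_frame_movie():
    img = np.zeros((40, 40))
    img[10:20, 10:20] = 200.0
    aligned, masks, offsets = preprocess_movie([gray_frame(img)])
    assert len(aligned) == len(masks) == 1 and offsets == [(0, 0)]


def test_foreground_grows_with_the_colony(small_movie):
    _, frames, _ = small_movie
    _, masks, _ = preprocess_movie(frames)
    areas = [m.mask.sum() for m in masks]
    growing = sum(b >= a for a, b in zip(areas, areas[1:]))
    assert growing >= 0.8 * (len(areas) - 1)


def test_alignment_repairs_a_drifting_copy(small_movie):
    _, frames, _ = small_movie
    ref = frames[-1]
    drifts = [(0, 0), (2, 1), (4, -1), (5, 3)]
    movie = [
        Frame(t, {c: translate_image(ref.channels[c], dx, dy) for c in ("r", "g", "b")})
        for t, (dx, dy) in enumerate(drifts)
    ]
    _, masks, offsets = preprocess_movie(movie)
    assert offsets == drifts
    base = masks[0].mask
    for m in masks[1:]:
        mismatch = np.logical_xor(base, m.mask).sum()
        assert mismatch <= 0.02 * base.sum()
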