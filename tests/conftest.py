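import numpy as np
import pytest

from patchtrace import SimConfig, simulate_movie


@pytest.fixture(scope="session")
def small_movie():
    """A 12-frame single-founder movie shared by preprocessing/detection tests."""
    cfg = SimConfig(
        frame_count=12,
        image_size=(220, 220),
        initial_cells=1,
        founder_positions=((110.0, 110.0),),
        seed=7,
    )
    frames, gt = simulate_movie(cfg)
    return cfg, frames, gt


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free version for mask ground-truth checks."""
    cfg = SimConfig(
        frame_count=8,
        image_size=(220, 220),
        initial_cells=1,
        founder_positions=((110.0, 110.0),),
        noise_sigma=0.0,
        seed=7,
    )
    frames, gt = simulate_movie(cfg)
    return cfg, frames, gt


def rho_map(cell, shape):
    """Normalized elliptical distance of every pixel to one simulated cell."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = cell.center
    co, si = np.cos(cell.orientation), np.sin(cell.orientation)
    u = (xx - cx) * co + (yy - cy) * si
    v = -(xx - cx) * si + (yy - cy) * co
    return np.sqrt((u / (cell.length / 2.0)) ** 2 + (v / (cell.width / 2.0)) ** 2)
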