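"""Frame alignment and foreground extraction.

Raw multichannel frames become (a) spatially aligned RGB frames and (b) one
binary foreground mask per frame. Binarization works on the fluorescence
channels, which carry a far better signal-to-noise ratio than phase
contrast: per-channel median denoise, optional white-tophat background
removal, fusion of the channels by per-pixel maximum, a global Otsu
threshold, then a morphological opening and closing. Alignment is rigid
integer-pixel translation (chamber drift is translational) estimated by
phase correlation between consecutive frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening, white_tophat
from skimage.registration import phase_cross_correlation

from .frames import BinaryFrame, Frame

log = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "align_frames", "binarize_frame", "preprocess_movie"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the binarization chain; radii in pixels, 0 disables a stage.

    ``background_radius`` defaults to 0 because the bundled simulator has a
    flat background; set it above the cell width to remove slowly varying
    illumination in real recordings.
    """

    denoise_radius: int = 1
    background_radius: int = 0
    threshold_method: str = "otsu"
    morph_open_radius: int = 1
    morph_close_radius: int = 1
    align: bool = True
    max_shift: int = 20

    def __post_init__(self) -> None:
        for name in ("denoise_radius", "background_radius",
                     "morph_open_radius", "morph_close_radius", "max_shift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.threshold_method != "otsu":
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


def align_frames(
    frames: list[Frame], max_shift: int = 20
) -> tuple[list[Frame], list[tuple[int, int]]]:
    """Register every frame onto its predecessor by phase correlation.

    Returns the aligned frames and one integer ``(dx, dy)`` offset per
    frame: the estimated displacement of the frame's content relative to
    frame 0 (so the aligned frame is the input shifted by ``(-dx, -dy)``).
    Frame 0 and frames without usable signal get offset (0, 0); offsets are
    clamped componentwise to ``max_shift``.
    """
    if not frames:
        raise ValueError("empty movie")
    aligned = [frames[0]]
    offsets: list[tuple[int, int]] = [(0, 0)]
    prev = frames[0].summed()
    for frame in frames[1:]:
        cur = frame.summed()
        if np.ptp(prev) == 0 or np.ptp(cur) == 0:
            dx = dy = 0
        else:
            # shift registering `cur` onto `prev`: prev ~ translate(cur, shift)
            shift, _, _ = phase_cross_correlation(prev, cur, upsample_factor=1)
            dy, dx = -int(round(shift[0])), -int(round(shift[1]))
            dx = int(np.clip(dx, -max_shift, max_shift))
            dy = int(np.clip(dy, -max_shift, max_shift))
        offsets.append((dx, dy))
        corrected = frame.translated(-dx, -dy)
        aligned.append(corrected)
        prev = corrected.summed()
    return aligned, offsets


def binarize_frame(frame: Frame, config: PreprocessConfig | None = None) -> BinaryFrame:
    """Foreground mask for one frame; a constant frame maps to all-background."""
    config = config or PreprocessConfig()
    chans = []
    for name in ("r", "g", "b"):
        chan = np.asarray(frame.channels[name], dtype=float)
        if config.denoise_radius > 0:
            chan = median_filter(chan, disk(config.denoise_radius))
        if config.background_radius > 0:
            chan = white_tophat(chan, disk(config.background_radius))
        chans.append(chan)
    fused = np.maximum.reduce(chans)
    if np.ptp(fused) == 0:  # Otsu is undefined on a constant image
        return BinaryFrame(frame.time_index, np.zeros(fused.shape, dtype=bool))
    mask = fused > threshold_otsu(fused)
    if config.morph_open_radius > 0:
        mask = opening(mask, disk(config.morph_open_radius))
    if config.morph_close_radius > 0:
        mask = closing(mask, disk(config.morph_close_radius))
    return BinaryFrame(frame.time_index, mask)


def preprocess_movie(
    frames: list[Frame], config: PreprocessConfig | None = None
) -> tuple[list[Frame], list[BinaryFrame], list[tuple[int, int]]]:
    """Align the movie, then binarize every frame.

    Returns ``(aligned_frames, masks, offsets)``; output lengths equal the
    input length. Per-frame failures are re-raised with the frame index.
    """
    config = config or PreprocessConfig()
    if config.align:
        aligned, offsets = align_frames(frames, config.max_shift)
    else:
        aligned, offsets = list(frames), [(0, 0)] * len(frames)
    masks = []
    for frame in aligned:
        try:
            masks.append(binarize_frame(frame, config))
        except Exception as exc:  # noqa: BLE001 - annotate with frame context
            raise RuntimeError(
                f"binarization failed at frame {frame.time_index}: {exc}"
            ) from exc
    return aligned, masks, offsets
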