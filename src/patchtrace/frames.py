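"""Image containers shared across the pipeline.

Coordinate convention, fixed project-wide: pixel origin at the top-left,
``x`` is the column index, ``y`` is the row index, both 0-based. A movie is
an ordered sequence of :class:`Frame` objects with consecutive time indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical fluorescence channel order
RGB_CHANNELS = ("r", "g", "b")


@dataclass
class Frame:
    """One multichannel image of a movie.

    Parameters
    ----------
    time_index:
        Position of the frame in the movie (frame number).
    channels:
        Mapping from channel name (``"r"``, ``"g"``, ``"b"``, optionally
        ``"l"`` for a luminance / phase-contrast channel) to a 2-D array.
        All channels must share one shape.
    """

    time_index: int
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def rgb(self) -> np.ndarray:
        """Stack the fluorescence channels into an (H, W, 3) float array."""
        return np.stack(
            [np.asarray(self.channels[c], dtype=float) for c in RGB_CHANNELS],
            axis=-1,
        )

    def summed(self) -> np.ndarray:
        """Sum of all channels; used for registration."""
        return sum(np.asarray(c, dtype=float) for c in self.channels.values())

    def translated(self, dx: int, dy: int) -> "Frame":
        """Return a copy rigidly shifted by integer (dx, dy), zero-filled."""
        out = {}
        for name, chan in self.channels.items():
            out[name] = translate_image(chan, dx, dy)
        return Frame(self.time_index, out)


@dataclass
class BinaryFrame:
    """Foreground mask for one frame (True = cell material)."""

    time_index: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def translate_image(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift ``img`` by integer (dx, dy) (x = columns, y = rows), zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape[:2]
    dx, dy = int(dx), int(dy)
    if abs(dx) >= w or abs(dy) >= h:
        return out
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = img[src_y, src_x]
    return out
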