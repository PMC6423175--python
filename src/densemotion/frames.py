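"""Core image containers.

Frames are plain 2-D float64 numpy arrays holding intensities in the 8-bit
range [0, 255].  Keeping real-valued intensities internally avoids
cumulative rounding across the operator chain; quantization to uint8
happens only on write.  :class:`ImageSeries` bundles an ordered stack of
equally sized frames with an optional inter-frame interval (metadata only —
all descriptors are reported per frame pair).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import EmptySeriesError, MixedDimensionsError

__all__ = ["ImageSeries", "as_frame", "to_uint8", "natural_key"]


def as_frame(a: np.ndarray) -> np.ndarray:
    """Coerce an array to a 2-D float64 frame without copying when possible."""
    f = np.asarray(a, dtype=np.float64)
    if f.ndim != 2 or f.size == 0:
        raise ValueError(f"a frame must be a non-empty 2-D array, got shape {f.shape}")
    return f


def to_uint8(frame: np.ndarray) -> np.ndarray:
    """Quantize a real-valued frame to 8-bit, clipping to [0, 255]."""
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


_NUM = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Numeric-aware sort key: ``frame_10`` sorts after ``frame_2``."""
    return tuple(int(p) if p.isdigit() else p for p in _NUM.split(str(name)))


@dataclass
class ImageSeries:
    """Ordered stack of equally sized grayscale frames.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, height, width)``; converted to float64.
    frame_interval
        Time between successive frames, in arbitrary units.  Metadata only.
    """

    data: np.ndarray
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim == 2:
            d = d[None]
        if d.ndim != 3:
            raise ValueError(f"series data must be (T, H, W), got shape {d.shape}")
        if d.shape[0] < 1 or d.shape[1] < 1 or d.shape[2] < 1:
            raise EmptySeriesError("series must contain at least one non-empty frame")
        self.data = d

    @classmethod
    def from_frames(cls, frames, frame_interval: float | None = None) -> "ImageSeries":
        frames = [as_frame(f) for f in frames]
        if not frames:
            raise EmptySeriesError("cannot build a series from zero frames")
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise MixedDimensionsError(f"frames have mixed dimensions: {sorted(shapes)}")
        return cls(np.stack(frames), frame_interval)

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    def __iter__(self):
        return iter(self.data)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.data.shape[1:]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    def map(self, func, *args, **kwargs) -> "ImageSeries":
        """Apply a frame operator to every frame, preserving metadata."""
        return ImageSeries(
            np.stack([func(f, *args, **kwargs) for f in self.data]),
            self.frame_interval,
        )
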