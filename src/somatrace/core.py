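"""Core data containers shared by every pipeline stage.

Coordinate convention (used everywhere in this package): boxes are 0-based,
half-open ``[x_min, x_max) x [y_min, y_max)`` with ``x`` = column and ``y`` =
row.  Pascal-VOC's 1-based inclusive convention is converted at the I/O
boundary only (see :mod:`somatrace.image_io`).  Movie frames are stored as a
``(T, H, W)`` array, so ``frames[t, y, x]`` addresses one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["BoundingBox", "MovieStack", "boxes_mask", "round_half_up"]


def round_half_up(value):
    """Round to nearest integer with ties going up (0.5 -> 1, 1.5 -> 2).

    numpy's default rounds half to even; box coordinate conversion needs a
    deterministic, direction-stable rule so the same sub-pixel box always
    maps to the same pixel box.
    """
    return np.floor(np.asarray(value, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box around one cell soma, with detector confidence.

    ``score`` is the detector confidence in [0, 1]; ``identity`` is filled in
    by the tracker once the box is bound to a persistent cell identity.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float = 1.0
    identity: Optional[int] = None

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: x [{self.x_min}, {self.x_max}), "
                f"y [{self.y_min}, {self.y_max})"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) center of the box."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )

    def scale(self, factor: float) -> "BoundingBox":
        """Divide coordinates by ``1/factor`` (multiply by ``factor``)."""
        return replace(
            self,
            x_min=self.x_min * factor,
            y_min=self.y_min * factor,
            x_max=self.x_max * factor,
            y_max=self.y_max * factor,
        )

    def clip(self, fov_shape: tuple[int, int]) -> "BoundingBox":
        """Clip to an (H, W) field of view.

        A box pushed entirely outside is frozen at the border with one pixel
        of extent so the identity it belongs to is never lost.
        """
        h, w = fov_shape
        x0 = min(max(self.x_min, 0.0), w - 1.0)
        y0 = min(max(self.y_min, 0.0), h - 1.0)
        x1 = max(min(self.x_max, float(w)), x0 + 1.0)
        y1 = max(min(self.y_max, float(h)), y0 + 1.0)
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def to_pixel(self) -> "BoundingBox":
        """Snap sub-pixel coordinates to the pixel grid (round half-up)."""
        x0, y0, x1, y1 = (
            round_half_up(self.x_min),
            round_half_up(self.y_min),
            round_half_up(self.x_max),
            round_half_up(self.y_max),
        )
        if x1 <= x0:
            x1 = x0 + 1
        if y1 <= y0:
            y1 = y0 + 1
        return replace(self, x_min=int(x0), y_min=int(y0), x_max=int(x1), y_max=int(y1))

    def pixel_slices(self, fov_shape: Optional[tuple[int, int]] = None):
        """(row_slice, col_slice) of the pixels inside the box.

        Sub-pixel edges are snapped with round-half-up; optionally clipped to
        the FOV.
        """
        b = self.to_pixel()
        y0, y1 = int(b.y_min), int(b.y_max)
        x0, x1 = int(b.x_min), int(b.x_max)
        if fov_shape is not None:
            h, w = fov_shape
            y0, y1 = max(y0, 0), min(y1, h)
            x0, x1 = max(x0, 0), min(x1, w)
        return slice(y0, y1), slice(x0, x1)

    def intersection_area(self, other: "BoundingBox") -> float:
        ix = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        iy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if ix <= 0.0 or iy <= 0.0:
            return 0.0
        return ix * iy


def boxes_mask(boxes: Sequence[BoundingBox], fov_shape: tuple[int, int]) -> np.ndarray:
    """Boolean (H, W) mask of pixels covered by the union of ``boxes``."""
    mask = np.zeros(fov_shape, dtype=bool)
    for box in boxes:
        rs, cs = box.pixel_slices(fov_shape)
        mask[rs, cs] = True
    return mask


@dataclass
class MovieStack:
    """An ordered stack of grayscale frames with acquisition metadata.

    frames: (T, H, W) array, integer or float.
    frame_rate: acquisition rate in Hz.
    pixel_size: lateral pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    frame_rate: float = 1.0
    pixel_size: float = 1.0
    bit_depth: Optional[int] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.bit_depth is None and np.issubdtype(self.frames.dtype, np.integer):
            self.bit_depth = self.frames.dtype.itemsize * 8

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fov_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames
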