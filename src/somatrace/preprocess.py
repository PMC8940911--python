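"""Detector-input preparation: projections, enhancement, registration, buffers.

The detector consumes small 8-bit, 3-channel images.  This module turns a
raw t-series into those inputs: temporal median (offline) or sliding/step
frame averages (online), optional rigid registration against the median
projection, intensity rescaling, bilinear upscaling, and channel
triplication.  The enhanced median projection (EMP) used for human
annotation — sharpening kernel, gamma 0.3, full-range renormalisation — also
lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .core import MovieStack

__all__ = [
    "AverageBuffer",
    "DetectorInput",
    "median_projection",
    "rigid_register",
    "enhance_projection",
    "prepare_detector_input",
    "push_frame",
    "buffer_lag_seconds",
    "upscale_factor_heuristic",
    "SHARPEN_KERNEL",
]

logger = logging.getLogger(__name__)

# Sharpening kernel used to build enhanced median projections: a high-boost
# filter whose coefficients sum to 4.
SHARPEN_KERNEL = np.array(
    [[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]], dtype=float
)


def median_projection(stack: MovieStack | np.ndarray) -> np.ndarray:
    """Per-pixel temporal median of the whole t-series."""
    frames = stack.frames if isinstance(stack, MovieStack) else np.asarray(stack)
    return np.median(frames, axis=0)


def rigid_register(
    stack: MovieStack,
    max_shift: float = 13.0,
    subpixel: bool = True,
    reference: Optional[np.ndarray] = None,
) -> tuple[MovieStack, np.ndarray]:
    """Align every frame to the raw median projection by phase correlation.

    Returns the registered stack and the per-frame correction vectors
    ``(dy, dx)`` that were applied (clipped to ``±max_shift`` pixels).  In
    sub-pixel mode corrections are quantised to 0.1 px; otherwise they are
    integers.  Featureless frames produce zero shift.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if reference is None:
        reference = np.median(frames, axis=0)

    shifts = np.zeros((len(frames), 2), dtype=float)
    out = np.empty_like(frames)
    upsample = 10 if subpixel else 1
    for t, frame in enumerate(frames):
        if np.ptp(frame) == 0 or np.ptp(reference) == 0:
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(
                reference, frame, upsample_factor=upsample, normalization=None
            )
        shift = np.clip(np.round(shift * 10) / 10, -max_shift, max_shift)
        shifts[t] = shift
        if np.all(shift == 0):
            out[t] = frame
        else:
            out[t] = ndimage.shift(frame, shift, order=1, mode="nearest")

    registered = MovieStack(
        frames=out.astype(stack.frames.dtype, copy=False)
        if np.issubdtype(stack.frames.dtype, np.floating)
        else out,
        frame_rate=stack.frame_rate,
        pixel_size=stack.pixel_size,
        bit_depth=stack.bit_depth,
    )
    return registered, shifts


def _to_uint8(image: np.ndarray) -> np.ndarray:
    """Linear rescale of an image onto the full 8-bit range (own min/max)."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.full(image.shape, 128, dtype=np.uint8)
    scaled = (image - lo) / (hi - lo) * 255.0
    return np.round(scaled).astype(np.uint8)


def enhance_projection(image: np.ndarray) -> np.ndarray:
    """Build the enhanced projection used for annotation.

    Steps: convert to 8-bit, sharpen with the high-boost kernel, apply a 0.3
    gamma on [0, 1]-normalised intensities, then linearly renormalise so the
    output spans the full 8-bit range.  A constant input has no range to
    stretch and maps to mid-gray.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("enhance_projection expects a single-channel image")
    if np.ptp(image) == 0:
        logger.warning("enhance_projection: constant image, returning mid-gray")
        return np.full(image.shape, 128, dtype=np.uint8)

    img8 = _to_uint8(image).astype(float)
    sharpened = ndimage.convolve(img8, SHARPEN_KERNEL, mode="reflect")
    lo, hi = sharpened.min(), sharpened.max()
    if hi == lo:
        logger.warning("enhance_projection: degenerate range after sharpening")
        return np.full(image.shape, 128, dtype=np.uint8)
    normalised = (sharpened - lo) / (hi - lo)
    corrected = normalised**0.3
    return _to_uint8(corrected)


@dataclass
class AverageBuffer:
    """Frame-downsampling buffer feeding the detector.

    ``sliding`` mode emits the arithmetic mean of the last ``n`` frames for
    every new frame once ``n`` frames have been seen; ``step`` mode emits the
    mean of each disjoint ``n``-frame block (the buffer is emptied after each
    emission), so outputs appear every ``n`` frames.
    """

    n: int
    mode: str = "sliding"
    _window: List[np.ndarray] = field(default_factory=list, repr=False)
    _running_sum: Optional[np.ndarray] = field(default=None, repr=False)
    frames_seen: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("buffer length n must be >= 1")
        if self.mode not in ("sliding", "step"):
            raise ValueError(f"unknown buffer mode: {self.mode!r}")

    def push(self, frame: np.ndarray) -> Optional[np.ndarray]:
        """Add one frame; return an averaged image when the buffer emits."""
        frame = np.asarray(frame, dtype=float)
        if self._window and frame.shape != self._window[0].shape:
            raise ValueError(
                f"frame shape {frame.shape} != buffered {self._window[0].shape}"
            )
        self.frames_seen += 1

        if self._running_sum is None:
            self._running_sum = np.zeros_like(frame)

        if self.mode == "sliding":
            self._window.append(frame)
            self._running_sum = self._running_sum + frame
            if len(self._window) > self.n:
                oldest = self._window.pop(0)
                self._running_sum = self._running_sum - oldest
            if len(self._window) == self.n:
                return self._running_sum / self.n
            return None

        # step mode
        self._window.append(frame)
        self._running_sum = self._running_sum + frame
        if len(self._window) == self.n:
            result = self._running_sum / self.n
            self._window.clear()
            self._running_sum = np.zeros_like(frame)
            return result
        return None

def buffer_lag_seconds(n: int, frame_rate: float) -> float:
    """Warm-up delay before the first detector input: n / frame_rate."""
    if n < 1 or frame_rate <= 0:
        raise ValueError("need n >= 1 and frame_rate > 0")
    return n / frame_rate


def push_frame(buffer: AverageBuffer, frame: np.ndarray) -> Optional[np.ndarray]:
    """Functional alias for :meth:`AverageBuffer.push`."""
    return buffer.push(frame)


@dataclass(frozen=True)
class DetectorInput:
    """8-bit, 3-channel, upscaled image ready for a detector."""

    image: np.ndarray  # (H', W', 3) uint8, all channels identical
    upscale_factor: float
    original_shape: tuple[int, int]

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("DetectorInput image must be (H, W, 3)")
        if img.dtype != np.uint8:
            raise ValueError("DetectorInput image must be uint8")


def prepare_detector_input(image: np.ndarray, upscale_factor: float = 1.0) -> DetectorInput:
    """Rescale to 8-bit, bilinearly upscale, and triplicate the channels."""
    if upscale_factor <= 0:
        raise ValueError("upscale_factor must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("prepare_detector_input expects a single-channel image")
    img8 = _to_uint8(image)
    if upscale_factor != 1.0:
        h, w = img8.shape
        new_shape = (int(round(h * upscale_factor)), int(round(w * upscale_factor)))
        scaled = resize(
            img8.astype(float),
            new_shape,
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        img8 = np.clip(np.round(scaled), 0, 255).astype(np.uint8)
    tri = np.repeat(img8[:, :, None], 3, axis=2)
    return DetectorInput(
        image=tri, upscale_factor=float(upscale_factor), original_shape=image.shape
    )


def upscale_factor_heuristic(
    fov_area: float,
    mean_box_area: float,
    calibration: tuple[float, float] = (1.0, 0.0),
    minimum: float = 0.6,
) -> float:
    """Predict the upscaling factor from the FOV / mean-soma area ratio.

    The factor grows linearly with ``sqrt(fov_area / mean_box_area)``;
    ``calibration`` is the (slope, intercept) of that line fitted on
    reference acquisitions.  The result is floored at ``minimum``.
    """
    if fov_area <= 0 or mean_box_area <= 0:
        raise ValueError("areas must be positive")
    slope, intercept = calibration
    factor = slope * float(np.sqrt(fov_area / mean_box_area)) + intercept
    factor = max(factor, minimum)
    if factor <= 0:
        raise ValueError(f"non-positive upscale factor: {factor}")
    return factor
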