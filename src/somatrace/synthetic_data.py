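"""Synthetic two-photon calcium-imaging movies with exact ground truth.

The generator emulates raster-scanned fluorescence acquisitions: bright,
roughly disk-shaped somata on a dim background, double-exponential
GECI-like transients driven by per-cell spike trains, a slow neuropil
signal shared by every pixel, per-pixel Gaussian shot-like noise, and
optional rigid lateral drift.  Every movie comes with its ground truth:
tightest bounding boxes, noiseless per-cell traces, and per-frame shift
vectors, so every downstream stage can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import BoundingBox, MovieStack
from .traces import TraceSet

__all__ = [
    "CellSpec",
    "SceneConfig",
    "SyntheticScene",
    "MotionProfile",
    "PlacementError",
    "generate_scene",
    "render_movie",
    "inject_motion",
    "default_scene_config",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed at the
    requested minimum spacing."""


@dataclass(frozen=True)
class CellSpec:
    """One simulated soma: geometry, brightness, and transient kinetics.

    rise_tau/decay_tau are the GECI kernel time constants in seconds;
    spike_times are frame indices at which a transient starts.
    """

    center: Tuple[float, float]  # (row, col), pixels
    radius: float  # pixels
    baseline_brightness: float = 50.0  # a.u.
    spike_times: Tuple[int, ...] = ()
    rise_tau: float = 0.1  # s
    decay_tau: float = 0.6  # s
    transient_amplitude: float = 100.0  # a.u.

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")
        if any(t < 0 for t in self.spike_times):
            raise ValueError("spike times must be non-negative frame indices")
        if tuple(sorted(self.spike_times)) != tuple(self.spike_times):
            raise ValueError("spike_times must be sorted")

    def gt_box(self) -> BoundingBox:
        """Tightest pixel box containing the soma disk (half-open)."""
        r0, c0 = self.center
        return BoundingBox(
            x_min=int(np.floor(c0 - self.radius)),
            y_min=int(np.floor(r0 - self.radius)),
            x_max=int(np.ceil(c0 + self.radius)) + 1,
            y_max=int(np.ceil(r0 + self.radius)) + 1,
        )


@dataclass
class SceneConfig:
    """Knobs of the generator; defaults mimic a cortical GCaMP acquisition."""

    fov_shape: Tuple[int, int] = (256, 256)  # (H, W) pixels
    pixel_size: float = 0.8  # µm/pixel
    frame_rate: float = 3.0  # Hz
    n_frames: int = 300
    n_cells: int = 20
    radius_range: Tuple[float, float] = (4.0, 6.0)  # pixels
    min_spacing_radii: float = 3.0  # pairwise center distance, in radii
    baseline: float = 20.0  # background offset, a.u.
    baseline_brightness_range: Tuple[float, float] = (40.0, 80.0)  # a.u.
    spike_rate: float = 0.15  # Hz per cell (Poisson)
    rise_tau: float = 0.1  # s
    decay_tau: float = 0.6  # s
    transient_amplitude: float = 100.0  # a.u.
    neuropil_amplitude: float = 0.0  # a.u.
    noise_sigma: float = 0.0  # a.u.


@dataclass
class SyntheticScene:
    """Generative description of a movie; render with :func:`render_movie`."""

    fov_shape: Tuple[int, int]
    pixel_size: float
    frame_rate: float
    n_frames: int
    cells: List[CellSpec]
    neuropil_amplitude: float = 0.0
    noise_sigma: float = 0.0
    baseline: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        h, w = self.fov_shape
        for cell in self.cells:
            r0, c0 = cell.center
            if not (0 <= r0 < h and 0 <= c0 < w):
                raise ValueError(f"cell center {cell.center} outside the FOV")
            if any(t >= self.n_frames for t in cell.spike_times):
                raise ValueError("spike time beyond the end of the movie")

    def gt_boxes(self) -> List[BoundingBox]:
        return [cell.gt_box() for cell in self.cells]


@dataclass(frozen=True)
class MotionProfile:
    """Rigid lateral drift: total displacement applied as a linear ramp.

    The displacement is expressed in micrometres (converted with the scene's
    pixel size) and ramps linearly from zero, starting at ``onset_frame``,
    over ``duration`` seconds.
    """

    total_displacement: float  # µm
    duration: float  # s
    onset_frame: int = 0
    direction: Tuple[float, float] = (1.0, 0.0)  # (dx, dy) unit vector

    def __post_init__(self):
        if self.total_displacement < 0:
            raise ValueError("total_displacement must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(
            self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
        )


def geci_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Double-exponential calcium-transient kernel, unit peak, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    k = np.zeros_like(t)
    pos = t >= 0
    k[pos] = np.exp(-t[pos] / decay_tau) - np.exp(-t[pos] / rise_tau)
    # peak of the difference-of-exponentials, in closed form
    t_peak = (rise_tau * decay_tau) / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return k / peak


def cell_intrinsic_trace(cell: CellSpec, n_frames: int, frame_rate: float) -> np.ndarray:
    """Noiseless somatic fluorescence of one cell at each frame time (a.u.)."""
    t = np.arange(n_frames, dtype=float) / frame_rate
    signal = np.full(n_frames, float(cell.baseline_brightness))
    for spike in cell.spike_times:
        signal += cell.transient_amplitude * geci_kernel(
            t - spike / frame_rate, cell.rise_tau, cell.decay_tau
        )
    return signal


def soma_profile(fov_shape: Tuple[int, int], center: Tuple[float, float], radius: float) -> np.ndarray:
    """Unit-amplitude soma footprint: hard disk with a 1-pixel Gaussian edge."""
    h, w = fov_shape
    rr, cc = np.ogrid[:h, :w]
    disk = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2).astype(float)
    return ndimage.gaussian_filter(disk, sigma=1.0)


def generate_scene(config: SceneConfig, seed: int) -> SyntheticScene:
    """Place cells and draw spike trains; deterministic given ``seed``.

    Cell centers are rejection-sampled so that every pairwise center distance
    is at least ``min_spacing_radii`` times the larger of the two radii.
    Raises :class:`PlacementError` when the requested density is infeasible.
    """
    rng = np.random.default_rng(seed)
    h, w = config.fov_shape
    r_lo, r_hi = config.radius_range

    centers: List[Tuple[float, float]] = []
    radii: List[float] = []
    max_attempts = 2000 * max(config.n_cells, 1)
    attempts = 0
    while len(centers) < config.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{config.n_cells} cells after "
                f"{max_attempts} attempts at spacing {config.min_spacing_radii} radii"
            )
        attempts += 1
        radius = float(rng.uniform(r_lo, r_hi))
        margin = radius + 2.0  # keep the smoothed edge inside the FOV
        r0 = float(rng.uniform(margin, h - margin))
        c0 = float(rng.uniform(margin, w - margin))
        ok = True
        for (pr, pc), prad in zip(centers, radii):
            spacing = config.min_spacing_radii * max(radius, prad)
            if (r0 - pr) ** 2 + (c0 - pc) ** 2 < spacing**2:
                ok = False
                break
        if ok:
            centers.append((r0, c0))
            radii.append(radius)

    cells = []
    for (r0, c0), radius in zip(centers, radii):
        expected = config.spike_rate * config.n_frames / config.frame_rate
        n_spikes = int(rng.poisson(expected))
        spikes = tuple(sorted(int(v) for v in rng.integers(0, config.n_frames, size=n_spikes)))
        cells.append(
            CellSpec(
                center=(r0, c0),
                radius=radius,
                baseline_brightness=float(rng.uniform(*config.baseline_brightness_range)),
                spike_times=spikes,
                rise_tau=config.rise_tau,
                decay_tau=config.decay_tau,
                transient_amplitude=config.transient_amplitude,
            )
        )

    return SyntheticScene(
        fov_shape=config.fov_shape,
        pixel_size=config.pixel_size,
        frame_rate=config.frame_rate,
        n_frames=config.n_frames,
        cells=cells,
        neuropil_amplitude=config.neuropil_amplitude,
        noise_sigma=config.noise_sigma,
        baseline=config.baseline,
        seed=seed,
    )


def neuropil_signal(n_frames: int, frame_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Slow common-mode signal: low-pass-filtered unit-variance Gaussian noise."""
    raw = rng.standard_normal(n_frames)
    # ~1 s correlation time at the given frame rate
    sigma = max(frame_rate, 1.0)
    smooth = ndimage.gaussian_filter1d(raw, sigma=sigma, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return smooth


def render_movie(scene: SyntheticScene) -> tuple[MovieStack, List[BoundingBox], TraceSet]:
    """Render a scene to (movie, ground-truth boxes, ground-truth traces).

    Each frame is
    ``baseline + sum_cells profile * intrinsic(t) + neuropil_amplitude * s(t) + noise``
    where ``intrinsic`` is the cell's baseline brightness plus its transient
    kernel train and ``s(t)`` is a shared slow signal.  The returned ground
    truth traces are the noiseless intrinsic signals (a.u.); averaging the
    noiseless movie over a cell's mask recovers them up to the footprint
    scale factor.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.fov_shape
    frames = np.full((scene.n_frames, h, w), float(scene.baseline), dtype=np.float32)

    gt_traces: dict[int, np.ndarray] = {}
    for idx, cell in enumerate(scene.cells):
        profile = soma_profile(scene.fov_shape, cell.center, cell.radius).astype(np.float32)
        intrinsic = cell_intrinsic_trace(cell, scene.n_frames, scene.frame_rate)
        gt_traces[idx] = intrinsic
        frames += intrinsic[:, None, None].astype(np.float32) * profile[None, :, :]

    if scene.neuropil_amplitude != 0:
        common = neuropil_signal(scene.n_frames, scene.frame_rate, rng)
        frames += (scene.neuropil_amplitude * common)[:, None, None].astype(np.float32)

    if scene.noise_sigma > 0:
        frames += rng.normal(0.0, scene.noise_sigma, size=frames.shape).astype(np.float32)

    stack = MovieStack(
        frames=frames,
        frame_rate=scene.frame_rate,
        pixel_size=scene.pixel_size,
        bit_depth=None,
    )
    traces = TraceSet.from_arrays(
        {i: tr for i, tr in gt_traces.items()},
        bg=np.full(scene.n_frames, scene.baseline, dtype=float),
        frame_rate=scene.frame_rate,
    )
    return stack, scene.gt_boxes(), traces


def motion_shifts(
    profile: MotionProfile, n_frames: int, frame_rate: float, pixel_size: float
) -> np.ndarray:
    """Per-frame cumulative (dx, dy) shifts in pixels for a linear drift ramp."""
    total_px = profile.total_displacement / pixel_size
    ramp_frames = max(int(round(profile.duration * frame_rate)), 1)
    shifts = np.zeros((n_frames, 2), dtype=float)
    for t in range(n_frames):
        if t < profile.onset_frame:
            frac = 0.0
        else:
            frac = min((t - profile.onset_frame + 1) / ramp_frames, 1.0)
        shifts[t, 0] = frac * total_px * profile.direction[0]
        shifts[t, 1] = frac * total_px * profile.direction[1]
    return shifts


def inject_motion(
    stack: MovieStack,
    profile: MotionProfile,
    gt_boxes: Sequence[BoundingBox],
    fill_value: Optional[float] = None,
    crop_margin_um: Optional[float] = None,
) -> tuple[MovieStack, List[List[BoundingBox]], np.ndarray]:
    """Apply a rigid lateral drift ramp to a movie; translate GT with it.

    Returns (shifted stack, per-frame GT boxes, per-frame shift log in
    pixels).  Off-FOV pixels are filled with the stack's modal baseline value
    (or ``fill_value``); setting ``crop_margin_um`` instead crops that margin
    from every side after shifting, the way a maximal-displacement crop
    removes the black bands a shift introduces.
    """
    if profile.onset_frame >= stack.n_frames:
        raise ValueError("onset_frame beyond the end of the stack")
    h, w = stack.fov_shape
    total_px = profile.total_displacement / stack.pixel_size
    if total_px >= min(h, w):
        raise ValueError("displacement exceeds the field of view")

    shifts = motion_shifts(profile, stack.n_frames, stack.frame_rate, stack.pixel_size)
    if fill_value is None:
        fill_value = float(np.min(stack.frames[0]))

    out = np.empty_like(np.asarray(stack.frames, dtype=np.float32))
    for t, frame in enumerate(stack.frames):
        dx, dy = shifts[t]
        if dx == 0 and dy == 0:
            out[t] = frame
        else:
            # ndimage.shift takes (row, col) = (dy, dx); bilinear interpolation
            out[t] = ndimage.shift(
                np.asarray(frame, dtype=np.float32),
                shift=(dy, dx),
                order=1,
                mode="constant",
                cval=fill_value,
            )

    shifted_gt: List[List[BoundingBox]] = []
    for t in range(stack.n_frames):
        dx, dy = shifts[t]
        shifted_gt.append([b.translate(dx, dy).clip((h, w)) for b in gt_boxes])

    if crop_margin_um is not None:
        m = int(np.ceil(crop_margin_um / stack.pixel_size))
        if 2 * m >= min(h, w):
            raise ValueError("crop margin larger than the field of view")
        out = out[:, m : h - m, m : w - m]
        shifted_gt = [
            [b.translate(-m, -m).clip((h - 2 * m, w - 2 * m)) for b in frame_boxes]
            for frame_boxes in shifted_gt
        ]

    moved = MovieStack(
        frames=out,
        frame_rate=stack.frame_rate,
        pixel_size=stack.pixel_size,
        bit_depth=stack.bit_depth,
    )
    return moved, shifted_gt, shifts


def default_scene_config(**overrides) -> SceneConfig:
    """The reference study conditions: 256x256 px, 300 frames, 20 somata."""
    cfg = SceneConfig()
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown scene parameter: {key}")
        setattr(cfg, key, value)
    return cfg
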