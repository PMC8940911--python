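"""Dynamic segmentation, background estimation, and trace assembly.

The soma signal of a cell at one frame is the arithmetic mean of the pixels
inside its bounding box whose intensity falls between the low and high
percentile of the box's own intensity distribution *for that frame* — the
mask is recomputed every frame, so a moving or re-shaped box never needs a
static segmentation.  The background (``bg``) is the mean of every pixel
outside all boxes, also recomputed per frame, and is subtracted from every
soma mean.  The online orchestrator wires buffers, detector, tracker, and
extractor together; its scheduling is a contract, not a mechanism: outputs
are identical however the work is interleaved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .core import BoundingBox, MovieStack, boxes_mask
from .detection import (
    DetectionSet,
    DetectorInterface,
    boxes_to_native,
    detect_image,
    make_detector,
    suppress_duplicates,
)
from .preprocess import (
    AverageBuffer,
    median_projection,
    prepare_detector_input,
    rigid_register,
)
from .tracking import IdentityRegistry, update_tracks
from .traces import TraceSet

__all__ = [
    "segment_box",
    "global_background",
    "local_background",
    "extract_frame",
    "run_online",
    "run_online_threaded",
    "run_offline",
    "OnlineState",
]

logger = logging.getLogger(__name__)


def segment_box(
    frame: np.ndarray,
    box: BoundingBox,
    p_low: float = 80.0,
    p_high: float = 95.0,
) -> tuple[np.ndarray, float]:
    """Percentile-window segmentation of one box in one frame.

    Returns ``(mask, soma_mean)``: the boolean mask (same shape as the box's
    pixel patch) of pixels whose intensity lies in the closed interval
    ``[P_low, P_high]`` of the box's intensity distribution, and the
    arithmetic mean of those pixels.  Percentiles use linear interpolation
    between order statistics.  A constant patch selects every pixel.
    """
    rs, cs = box.pixel_slices(frame.shape)
    patch = np.asarray(frame[rs, cs], dtype=float)
    if patch.size == 0:
        raise ValueError(f"box {box} contains no pixels after clipping")
    lo, hi = np.percentile(patch, [p_low, p_high])
    mask = (patch >= lo) & (patch <= hi)
    if not mask.any():
        # only possible through floating-point pathologies; fall back to
        # the nearest pixel to the window
        mask = patch == patch.flat[np.argmin(np.abs(patch - lo).ravel())]
    return mask, float(patch[mask].mean())


def global_background(frame: np.ndarray, boxes: Sequence[BoundingBox]) -> float:
    """Mean of all pixels outside the union of the boxes, for this frame."""
    frame = np.asarray(frame, dtype=float)
    if not boxes:
        return float(frame.mean())
    covered = boxes_mask(boxes, frame.shape)
    outside = ~covered
    if not outside.any():
        raise ValueError("boxes cover the entire field of view: no background pixels")
    return float(frame[outside].mean())


def local_background(
    frame: np.ndarray,
    box: BoundingBox,
    all_boxes: Sequence[BoundingBox],
) -> float:
    """Mean of the cell's surround: a concentric box of doubled side lengths,
    excluding the cell's own box and any other bounding box.

    Returns NaN (and logs) when no eligible pixel remains.
    """
    frame = np.asarray(frame, dtype=float)
    w = box.x_max - box.x_min
    h = box.y_max - box.y_min
    big = BoundingBox(
        x_min=box.x_min - w / 2.0,
        y_min=box.y_min - h / 2.0,
        x_max=box.x_max + w / 2.0,
        y_max=box.y_max + h / 2.0,
        score=box.score,
    ).clip(frame.shape)
    eligible = np.zeros(frame.shape, dtype=bool)
    rs, cs = big.pixel_slices(frame.shape)
    eligible[rs, cs] = True
    eligible &= ~boxes_mask([box], frame.shape)
    others = [b for b in all_boxes if b is not box]
    if others:
        eligible &= ~boxes_mask(others, frame.shape)
    if not eligible.any():
        logger.warning("local_background: no eligible pixels around %s", box)
        return float("nan")
    return float(frame[eligible].mean())


def extract_frame(
    frame: np.ndarray,
    registry: IdentityRegistry,
    traces: TraceSet,
    p_low: float = 80.0,
    p_high: float = 95.0,
    extract_inactive: bool = True,
) -> TraceSet:
    """Append one frame of background-subtracted soma means to the traces.

    Every identity — active and, by default, inactive at its last
    (rigid-shifted) box — gets ``soma_mean - bg``.  A failing segmentation
    for one identity is logged and recorded as missing without aborting the
    frame.
    """
    boxes = registry.current_boxes()
    bg = global_background(frame, boxes)
    values = {}
    for ident_id, identity in sorted(registry.identities.items()):
        if not identity.active and not extract_inactive:
            continue
        try:
            _, soma = segment_box(frame, identity.box, p_low=p_low, p_high=p_high)
        except ValueError as exc:
            logger.warning("extract_frame: identity %d skipped: %s", ident_id, exc)
            values[ident_id] = float("nan")
            continue
        values[ident_id] = soma - bg
    traces.append_frame(bg, values)
    return traces


@dataclass
class OnlineState:
    """Everything the online orchestrator carries between frames."""

    buffer: AverageBuffer
    registry: IdentityRegistry
    traces: TraceSet
    frame_counter: int = 0
    config: Optional[PipelineConfig] = None
    detections: List[DetectionSet] = field(default_factory=list)
    event_log: List[dict] = field(default_factory=list)


def _resolve_detector(config: PipelineConfig, detector: Optional[DetectorInterface]):
    if detector is not None:
        return detector
    return make_detector(config.detector, model_path=config.model_path)


def run_online(
    frame_source: Iterable[np.ndarray] | MovieStack,
    config: Optional[PipelineConfig] = None,
    detector: Optional[DetectorInterface] = None,
    frame_rate: Optional[float] = None,
) -> tuple[TraceSet, IdentityRegistry, List[dict]]:
    """Stream frames through buffer -> detector -> tracker -> extractor.

    Per frame: push to the averaging buffer; when the buffer emits, run the
    detector, suppress duplicates, and update the tracks.  Every frame,
    regardless of the detection cadence, extract one trace sample per known
    identity.  The result is invariant to how the work is scheduled; this
    sequential implementation is the reference the concurrency contract is
    defined against.
    """
    if config is None:
        config = PipelineConfig()
    det = _resolve_detector(config, detector)

    if isinstance(frame_source, MovieStack):
        frame_rate = frame_source.frame_rate
        frames: Iterable[np.ndarray] = frame_source.frames
    else:
        frames = frame_source
    if frame_rate is None:
        frame_rate = 1.0

    state = OnlineState(
        buffer=AverageBuffer(n=config.n_frames, mode=config.mode),
        registry=None,  # set at first frame, once the FOV shape is known
        traces=TraceSet(frame_rate=frame_rate),
        config=config,
    )

    fov_shape: Optional[Tuple[int, int]] = None
    upscale = config.upscale_factor if config.upscale_factor is not None else 1.0

    for frame in frames:
        frame = np.asarray(frame)
        if fov_shape is None:
            fov_shape = frame.shape
            state.registry = IdentityRegistry(fov_shape=fov_shape)
        elif frame.shape != fov_shape:
            state.event_log.append(
                {"stage": "stream", "frame": state.frame_counter, "error": "shape change"}
            )
            raise RuntimeError(
                f"frame shape changed mid-stream at frame {state.frame_counter}: "
                f"{frame.shape} != {fov_shape}; state dumped to the event log"
            )

        averaged = state.buffer.push(frame)
        if averaged is not None:
            detections = detect_image(
                averaged,
                det,
                upscale_factor=upscale,
                score_threshold=config.score_threshold,
                nms_threshold=config.nms_threshold,
                frame_index=state.frame_counter,
            )
            update_tracks(
                state.registry,
                detections,
                new_id_threshold=config.new_id_threshold,
                matching=config.matching,
            )
            state.detections.append(detections)
            state.event_log.append(
                {
                    "stage": "detect",
                    "frame": state.frame_counter,
                    "n_boxes": len(detections.boxes),
                    "n_identities": len(state.registry),
                }
            )

        extract_frame(
            frame,
            state.registry,
            state.traces,
            p_low=config.p_low,
            p_high=config.p_high,
            extract_inactive=config.extract_inactive,
        )
        state.frame_counter += 1

    return state.traces, state.registry, state.event_log


def run_online_threaded(
    frame_source: Iterable[np.ndarray] | MovieStack,
    config: Optional[PipelineConfig] = None,
    detector: Optional[DetectorInterface] = None,
    frame_rate: Optional[float] = None,
    queue_size: int = 8,
) -> tuple[TraceSet, IdentityRegistry, List[dict]]:
    """Producer/consumer variant of :func:`run_online`.

    One thread replays frames into a bounded queue (standing in for a
    microscope pushing frames), the other runs the pipeline.  Scheduling is
    a contract, not a mechanism: the outputs are identical to the
    sequential reference implementation.
    """
    import queue as queue_mod
    import threading

    if isinstance(frame_source, MovieStack):
        frame_rate = frame_source.frame_rate
        frames: Iterable[np.ndarray] = frame_source.frames
    else:
        frames = frame_source

    q: "queue_mod.Queue" = queue_mod.Queue(maxsize=queue_size)
    _DONE = object()

    def producer():
        for frame in frames:
            q.put(frame)
        q.put(_DONE)

    def consume():
        while True:
            item = q.get()
            if item is _DONE:
                return
            yield item

    thread = threading.Thread(target=producer, daemon=True)
    thread.start()
    try:
        result = run_online(consume(), config=config, detector=detector, frame_rate=frame_rate)
    finally:
        thread.join(timeout=10)
    return result


def run_offline(
    stack: MovieStack,
    config: Optional[PipelineConfig] = None,
    detector: Optional[DetectorInterface] = None,
) -> tuple[TraceSet, IdentityRegistry]:
    """Single detection on the median projection, projected to every frame.

    Optional rigid registration, then: median projection -> detector input ->
    one detection -> duplicate suppression -> the same static box set is
    applied to every frame for extraction.
    """
    if config is None:
        config = PipelineConfig()
    det = _resolve_detector(config, detector)

    if config.register:
        stack, _ = rigid_register(stack, max_shift=config.max_shift)

    projection = median_projection(stack)
    upscale = config.upscale_factor if config.upscale_factor is not None else 1.0
    detections = detect_image(
        projection,
        det,
        upscale_factor=upscale,
        score_threshold=config.score_threshold,
        nms_threshold=config.nms_threshold,
        frame_index=0,
    )

    registry = IdentityRegistry(fov_shape=stack.fov_shape)
    for box in detections.boxes:
        registry.add(box, frame_index=0)

    traces = TraceSet(frame_rate=stack.frame_rate)
    for frame in stack:
        extract_frame(
            frame,
            registry,
            traces,
            p_low=config.p_low,
            p_high=config.p_high,
            extract_inactive=config.extract_inactive,
        )
    return traces, registry
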