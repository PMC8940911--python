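"""Detector interface, overlap measures, duplicate suppression, tiling.

The detector is pluggable: anything exposing ``detect(DetectorInput) ->
list[BoundingBox]`` works.  A classical multiscale Laplacian-of-Gaussian
blob detector is provided as the reference implementation so the whole
pipeline runs on a CPU with no trained model.

Two overlap measures coexist and must not be confused:

* :func:`pair_overlap` — intersection area divided by the *sum* of the two
  box areas.  This is the measure the detection/tracking thresholds (20%,
  25%) are defined on.  It is at most 0.5 (identical boxes).
* :func:`standard_iou` — intersection over union, the conventional measure,
  provided for interoperability and used for the mean-IoU quality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .core import BoundingBox, MovieStack, round_half_up
from .preprocess import (
    AverageBuffer,
    DetectorInput,
    median_projection,
    prepare_detector_input,
)

__all__ = [
    "DetectorInterface",
    "DetectorLoadError",
    "DetectionSet",
    "TilingPlan",
    "pair_overlap",
    "standard_iou",
    "suppress_duplicates",
    "ReferenceBlobDetector",
    "reference_blob_detector",
    "cnn_adapter",
    "boxes_to_native",
    "detect_image",
    "plan_tiles",
    "detect_tiled",
    "grid_search_offline",
    "grid_search_online",
]


# --------------------------------------------------------------------------
# Overlap measures
# --------------------------------------------------------------------------

def pair_overlap(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over the sum of the two areas; in [0, 0.5].

    Symmetric; 0 iff the boxes are disjoint; 0.5 for identical boxes.  All
    20%/25% duplicate and new-identity thresholds refer to this measure.
    """
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area)


def standard_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Conventional intersection-over-union, in [0, 1]."""
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def intersection_over_min(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over the smaller box area, in [0, 1]."""
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / min(a.area, b.area)


# --------------------------------------------------------------------------
# Duplicate suppression
# --------------------------------------------------------------------------

def _nms_sort_key(box: BoundingBox):
    # descending score; ties resolved by smaller (y_min, x_min)
    return (-box.score, box.y_min, box.x_min)


def suppress_duplicates(
    boxes: Sequence[BoundingBox],
    overlap_threshold: float = 0.2,
    overlap_fn=pair_overlap,
) -> List[BoundingBox]:
    """Greedy non-maximum suppression keeping the highest-scoring box.

    Boxes overlapping a kept box by more than ``overlap_threshold`` (in the
    area-sum measure by default) are duplicates and removed.
    Deterministic under score ties (smaller ``(y_min, x_min)`` wins).
    """
    remaining = sorted(boxes, key=_nms_sort_key)
    kept: List[BoundingBox] = []
    for box in remaining:
        if all(overlap_fn(box, k) <= overlap_threshold for k in kept):
            kept.append(box)
    return kept


# --------------------------------------------------------------------------
# Detector interface and implementations
# --------------------------------------------------------------------------

@runtime_checkable
class DetectorInterface(Protocol):
    """Contract for detectors: boxes in the DetectorInput coordinate frame,
    scores in [0, 1]."""

    descriptor: str

    def detect(self, detector_input: DetectorInput) -> List[BoundingBox]: ...


class DetectorLoadError(RuntimeError):
    """A detector model could not be loaded."""


@dataclass
class ReferenceBlobDetector:
    """Multiscale Laplacian-of-Gaussian blob detector.

    A classical, CPU-only reference detector: somata are bright blobs, so
    local maxima of the scale-normalised LoG response across a range of
    scales mark candidate cells.  Each blob becomes a square box of side
    ``2*sqrt(2)*sigma`` centred on the response peak; scores are the blob
    responses normalised to [0, 1] within the image.
    """

    scale_range: tuple[float, float] = (2.0, 8.0)
    num_scales: int = 8
    response_floor: float = 0.02
    descriptor: str = field(default="reference-blob-log/1", repr=False)

    def detect(self, detector_input: DetectorInput) -> List[BoundingBox]:
        from skimage.feature import blob_log

        image = detector_input.image[:, :, 0].astype(float) / 255.0
        if np.ptp(image) == 0:
            return []
        lo, hi = self.scale_range
        blobs = blob_log(
            image,
            min_sigma=lo,
            max_sigma=hi,
            num_sigma=self.num_scales,
            threshold=self.response_floor,
        )
        if blobs.size == 0:
            return []

        # scale-normalised response at each blob's own scale
        responses = np.empty(len(blobs))
        log_cache: dict[float, np.ndarray] = {}
        h, w = image.shape
        for i, (r, c, sigma) in enumerate(blobs):
            if sigma not in log_cache:
                log_cache[sigma] = -(sigma**2) * ndimage.gaussian_laplace(image, sigma)
            responses[i] = log_cache[sigma][int(r), int(c)]
        max_resp = responses.max()
        if max_resp <= 0:
            return []

        boxes: List[BoundingBox] = []
        for (r, c, sigma), resp in zip(blobs, responses):
            if resp <= 0:
                continue
            half = np.sqrt(2.0) * sigma
            box = BoundingBox(
                x_min=c - half,
                y_min=r - half,
                x_max=c + half,
                y_max=r + half,
                score=float(np.clip(resp / max_resp, 0.0, 1.0)),
            ).clip((h, w))
            boxes.append(box)
        return boxes


def reference_blob_detector(
    detector_input: DetectorInput,
    scale_range: tuple[float, float] = (2.0, 8.0),
    response_floor: float = 0.02,
) -> List[BoundingBox]:
    """Functional form of :class:`ReferenceBlobDetector`."""
    det = ReferenceBlobDetector(scale_range=scale_range, response_floor=response_floor)
    return det.detect(detector_input)


def cnn_adapter(model_path) -> DetectorInterface:
    """Load an externally trained single-class box-regression model.

    The network itself is an external artifact; this adapter only binds it to
    the :class:`DetectorInterface` contract through a generic ONNX inference
    runtime.  Absence of a model (or of a runtime) never blocks the rest of
    the library: a :class:`DetectorLoadError` points the caller at the
    reference blob detector instead.
    """
    path = Path(model_path)
    if not path.is_file():
        raise DetectorLoadError(
            f"model file not found: {path}. Use detector='reference' "
            "(the Laplacian-of-Gaussian reference detector) if no trained "
            "model is available."
        )
    try:
        import onnxruntime  # noqa: F401
    except ImportError as exc:
        raise DetectorLoadError(
            "no inference runtime available to load the model; install "
            "onnxruntime or use detector='reference'."
        ) from exc

    session = onnxruntime.InferenceSession(str(path))

    @dataclass
    class _OnnxDetector:
        descriptor: str = f"cnn-onnx:{path.name}"

        def detect(self, detector_input: DetectorInput) -> List[BoundingBox]:
            img = detector_input.image.astype(np.float32)[None]
            outputs = session.run(None, {session.get_inputs()[0].name: img})
            raw_boxes, scores = outputs[0][0], outputs[1][0]
            h, w = detector_input.image.shape[:2]
            boxes = []
            for (x0, y0, x1, y1), s in zip(raw_boxes, scores):
                if x1 <= x0 or y1 <= y0 or s < 0:
                    continue
                boxes.append(
                    BoundingBox(
                        float(x0), float(y0), float(x1), float(y1),
                        score=float(np.clip(s, 0.0, 1.0)),
                    ).clip((h, w))
                )
            return boxes

    return _OnnxDetector()


def make_detector(name: str = "reference", model_path=None, **kwargs) -> DetectorInterface:
    """Detector plug-in discovery by name: ``reference`` or ``cnn``."""
    if name == "reference":
        allowed = {"scale_range", "num_scales", "response_floor"}
        return ReferenceBlobDetector(**{k: v for k, v in kwargs.items() if k in allowed})
    if name == "cnn":
        if model_path is None:
            raise DetectorLoadError("detector 'cnn' requires model_path")
        return cnn_adapter(model_path)
    raise ValueError(f"unknown detector: {name!r}")


# --------------------------------------------------------------------------
# Detection sets and the native-coordinate mapping
# --------------------------------------------------------------------------

def boxes_to_native(
    boxes: Sequence[BoundingBox], upscale_factor: float
) -> List[BoundingBox]:
    """Map detector-frame boxes back to native pixels.

    Coordinates are divided by the upscale factor and rounded half-up; this
    is the single place where the scale conversion happens.
    """
    if upscale_factor == 1.0:
        return [b.to_pixel() for b in boxes]
    return [b.scale(1.0 / upscale_factor).to_pixel() for b in boxes]


@dataclass
class DetectionSet:
    """Score-filtered, duplicate-suppressed boxes for one detector input."""

    frame_index: int
    boxes: List[BoundingBox]
    score_threshold: float = 0.0


def detect_image(
    image: np.ndarray,
    detector: DetectorInterface,
    upscale_factor: float = 1.0,
    score_threshold: float = 0.0,
    nms_threshold: float = 0.2,
    frame_index: int = 0,
) -> DetectionSet:
    """Prepare an image, run the detector, map back, filter, and suppress."""
    det_input = prepare_detector_input(image, upscale_factor)
    raw = detector.detect(det_input)
    native = boxes_to_native(raw, upscale_factor)
    h, w = image.shape[:2]
    native = [b.clip((h, w)) for b in native if b.score >= score_threshold]
    kept = suppress_duplicates(native, overlap_threshold=nms_threshold)
    return DetectionSet(frame_index=frame_index, boxes=kept, score_threshold=score_threshold)


# --------------------------------------------------------------------------
# Tiled detection for mesoscopic fields of view
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TilingPlan:
    """Where to cut a large FOV into detector-sized tiles."""

    tile_size: int
    overlap: int
    offsets: tuple[tuple[int, int], ...]  # (row, col) of each tile origin
    batch_size: int = 8


def _axis_offsets(length: int, tile: int, stride: int) -> List[int]:
    offsets = list(range(0, length - tile + 1, stride))
    if not offsets:
        offsets = [0]
    if offsets[-1] + tile < length:
        offsets.append(length - tile)
    return offsets


def plan_tiles(
    fov_shape: tuple[int, int],
    tile_size: int = 128,
    overlap: int = 28,
    batch_size: int = 8,
) -> TilingPlan:
    """Strided tile grid with full coverage.

    Offsets advance by ``tile_size - overlap``; when the strided grid leaves
    uncovered pixels at the end of an axis, a final tile is anchored at
    ``dim - tile_size``.
    """
    h, w = fov_shape
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile {tile_size} larger than FOV {fov_shape}")
    if overlap >= tile_size:
        raise ValueError("overlap must be smaller than tile_size")
    stride = tile_size - overlap
    rows = _axis_offsets(h, tile_size, stride)
    cols = _axis_offsets(w, tile_size, stride)
    offsets = tuple((r, c) for r in rows for c in cols)
    return TilingPlan(tile_size=tile_size, overlap=overlap, offsets=offsets, batch_size=batch_size)


def detect_tiled(
    image: np.ndarray,
    detector: DetectorInterface,
    plan: Optional[TilingPlan] = None,
    score_threshold: float = 0.0,
    upscale_factor: float = 1.0,
    nms_threshold: float = 0.2,
) -> DetectionSet:
    """Run the detector per tile, recombine, and suppress seam duplicates.

    Tiles are processed in batches of ``plan.batch_size``; batching is purely
    an execution detail — the result is independent of it.
    """
    if plan is None:
        plan = plan_tiles(image.shape[:2])
    merged: List[BoundingBox] = []
    offsets = list(plan.offsets)
    for start in range(0, len(offsets), plan.batch_size):
        batch = offsets[start : start + plan.batch_size]
        for r0, c0 in batch:
            tile = image[r0 : r0 + plan.tile_size, c0 : c0 + plan.tile_size]
            det = detect_image(
                tile,
                detector,
                upscale_factor=upscale_factor,
                score_threshold=score_threshold,
                nms_threshold=1.0,  # defer suppression to the merged set
            )
            merged.extend(b.translate(c0, r0) for b in det.boxes)
    kept = suppress_duplicates(merged, overlap_threshold=nms_threshold)
    return DetectionSet(frame_index=0, boxes=kept, score_threshold=score_threshold)


# --------------------------------------------------------------------------
# Parameter grid searches
# --------------------------------------------------------------------------

def _default_upscale_grid() -> np.ndarray:
    return np.round(np.arange(0.6, 3.4 + 1e-9, 0.2), 10)


def _default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 0.95 + 1e-9, 0.05), 10)


def grid_search_offline(
    stack: MovieStack,
    gt: Sequence[BoundingBox],
    detector: DetectorInterface,
    upscale_grid: Optional[Sequence[float]] = None,
    threshold_grid: Optional[Sequence[float]] = None,
    nms_threshold: float = 0.2,
):
    """Exhaustive (upscale, score-threshold) search maximising offline F-1.

    Returns ``(best_upscale, best_threshold), surface`` where ``surface`` is
    a DataFrame with one row per grid point.  Ties break toward smaller
    upscale, then higher threshold.
    """
    import pandas as pd

    from .analysis import match_detections

    upscales = np.asarray(upscale_grid if upscale_grid is not None else _default_upscale_grid(), float)
    thresholds = np.asarray(threshold_grid if threshold_grid is not None else _default_threshold_grid(), float)

    projection = median_projection(stack)
    rows = []
    for up in upscales:
        det_input = prepare_detector_input(projection, up)
        raw = detector.detect(det_input)
        native_all = boxes_to_native(raw, up)
        h, w = projection.shape
        native_all = [b.clip((h, w)) for b in native_all]
        for thr in thresholds:
            candidate = [b for b in native_all if b.score >= thr]
            kept = suppress_duplicates(candidate, overlap_threshold=nms_threshold)
            report = match_detections(kept, list(gt))
            rows.append(
                {
                    "upscale": float(up),
                    "threshold": float(thr),
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                }
            )
    surface = pd.DataFrame(rows)
    best = surface.sort_values(
        ["f1", "upscale", "threshold"], ascending=[False, True, False]
    ).iloc[0]
    return (float(best["upscale"]), float(best["threshold"])), surface


def grid_search_online(
    stack: MovieStack,
    gt: Sequence[BoundingBox],
    detector: DetectorInterface,
    n_grid: Sequence[int] = (1, 5, 10, 20),
    threshold_grid: Optional[Sequence[float]] = None,
    mode: str = "sliding",
    upscale_factor: float = 1.0,
    new_id_threshold: float = 0.2,
    nms_threshold: float = 0.2,
):
    """(frame-downsampling n, score-threshold) search maximising online F-1.

    For each ``n`` the movie is replayed through an averaging buffer; each
    emission is detected and fed to the tracker, and F-1 is measured on the
    final tracked box set against the ground truth.
    """
    import pandas as pd

    from .analysis import match_detections
    from .tracking import IdentityRegistry, update_tracks

    thresholds = np.asarray(threshold_grid if threshold_grid is not None else _default_threshold_grid(), float)
    h, w = stack.fov_shape

    rows = []
    for n in n_grid:
        # one detector pass per emission, shared by all thresholds
        buffer = AverageBuffer(n=int(n), mode=mode)
        emissions_raw: List[List[BoundingBox]] = []
        for frame in stack:
            averaged = buffer.push(frame)
            if averaged is None:
                continue
            det_input = prepare_detector_input(averaged, upscale_factor)
            raw = detector.detect(det_input)
            native = [b.clip((h, w)) for b in boxes_to_native(raw, upscale_factor)]
            emissions_raw.append(native)
        for thr in thresholds:
            registry = IdentityRegistry(fov_shape=(h, w))
            for k, native in enumerate(emissions_raw):
                candidate = [b for b in native if b.score >= thr]
                kept = suppress_duplicates(candidate, overlap_threshold=nms_threshold)
                update_tracks(
                    registry,
                    DetectionSet(frame_index=k, boxes=kept, score_threshold=thr),
                    new_id_threshold=new_id_threshold,
                )
            final_boxes = registry.current_boxes()
            report = match_detections(final_boxes, list(gt))
            rows.append(
                {
                    "n": int(n),
                    "threshold": float(thr),
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                }
            )
    surface = pd.DataFrame(rows)
    best = surface.sort_values(
        ["f1", "n", "threshold"], ascending=[False, True, False]
    ).iloc[0]
    return (int(best["n"]), float(best["threshold"])), surface
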