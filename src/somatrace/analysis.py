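"""Detection metrics, consensus annotation, events, SNR, correlation analytics.

Detection quality is scored by greedy one-to-one matching of predicted
against ground-truth boxes.  The matching measure for the 0.5 surface-overlap
cutoff is intersection over the smaller box area by default (standard IoU is
available); the mean-IoU quality score over matched pairs always uses
standard IoU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial.distance import pdist

from .core import BoundingBox
from .detection import DetectionSet, intersection_over_min, standard_iou
from .traces import TraceSet

__all__ = [
    "MetricsReport",
    "EventList",
    "match_detections",
    "f1_from_counts",
    "consensus_merge",
    "detect_events",
    "snr",
    "correlation_matrix",
    "dendrogram_order",
    "gaussian_smooth",
    "evaluate_online_run",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Detection-vs-ground-truth counts and scores."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    mean_iou: float
    matched_pairs: List[Tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "mean_iou": self.mean_iou,
        }


def f1_from_counts(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision < 0 or recall < 0 or precision > 1 or recall > 1:
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def match_detections(
    pred: Sequence[BoundingBox],
    gt: Sequence[BoundingBox],
    overlap_cutoff: float = 0.5,
    measure: str = "iomin",
) -> MetricsReport:
    """Greedy one-to-one matching of predictions to ground truth.

    Candidate pairs are ranked by descending overlap (intersection over the
    smaller box by default, ``measure='iou'`` for standard IoU); accepted
    pairs with overlap above ``overlap_cutoff`` are true positives.
    Unmatched predictions are false positives, unmatched ground-truth boxes
    false negatives.  ``mean_iou`` is the mean *standard* IoU over the
    matched pairs.  Conventions: precision is 0 when there are no
    predictions; recall is 1 when there is no ground truth.
    """
    overlap_fn: Callable[[BoundingBox, BoundingBox], float]
    overlap_fn = intersection_over_min if measure == "iomin" else standard_iou

    pairs = [
        (overlap_fn(p, g), i, j)
        for i, p in enumerate(pred)
        for j, g in enumerate(gt)
        if overlap_fn(p, g) > overlap_cutoff
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    matched: List[Tuple[int, int, float]] = []
    for ov, i, j in pairs:
        if i in used_p or j in used_g:
            continue
        matched.append((i, j, ov))
        used_p.add(i)
        used_g.add(j)

    tp = len(matched)
    fp = len(pred) - tp
    fn = len(gt) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    f1 = f1_from_counts(precision, recall)
    mean_iou = (
        float(np.mean([standard_iou(pred[i], gt[j]) for i, j, _ in matched]))
        if matched
        else 0.0
    )
    return MetricsReport(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        mean_iou=mean_iou, matched_pairs=matched,
    )


def consensus_merge(
    gt1: Sequence[BoundingBox],
    gt2: Sequence[BoundingBox],
    overlap_threshold: float = 0.5,
    measure: str = "iomin",
) -> tuple[List[BoundingBox], List[BoundingBox]]:
    """Merge two graders' annotations of the same image.

    Pairs overlapping above the threshold enter the consensus (one box per
    pair — grader 1's, by convention); every remaining box from either
    grader goes to the disputed list for manual adjudication.
    """
    overlap_fn = intersection_over_min if measure == "iomin" else standard_iou
    pairs = [
        (overlap_fn(a, b), i, j)
        for i, a in enumerate(gt1)
        for j, b in enumerate(gt2)
        if overlap_fn(a, b) > overlap_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    consensus: List[BoundingBox] = []
    for _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        consensus.append(gt1[i])
        used1.add(i)
        used2.add(j)
    disputed = [b for i, b in enumerate(gt1) if i not in used1]
    disputed += [b for j, b in enumerate(gt2) if j not in used2]
    return consensus, disputed


@dataclass
class EventList:
    """Calcium events of one trace: peak frame indices and amplitudes."""

    indices: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("event indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


def detect_events(
    trace: np.ndarray,
    window: int = 15,
    prominence: float = 7.0,
    min_height: float = 3.0,
) -> EventList:
    """Savitzky–Golay smoothing followed by positive-going peak picking.

    The trace is smoothed with a second-order Savitzky–Golay filter over
    ``window`` frames; local maxima with at least the given prominence and
    height are calcium events.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < window:
        raise ValueError(f"trace of length {trace.size} shorter than window {window}")
    smoothed = savgol_filter(trace, window_length=window, polyorder=2)
    peaks, props = find_peaks(smoothed, prominence=prominence, height=(min_height, None))
    return EventList(indices=peaks, amplitudes=props.get("peak_heights", np.zeros(0)))


def snr(values: np.ndarray) -> float:
    """Mean divided by the (population) standard deviation.

    Applies to a whole t-series, the pixels of one ROI, or a trace.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std()  # population form (divide by N)
    if sd == 0:
        raise ValueError("zero standard deviation: SNR undefined")
    return float(values.mean() / sd)


def correlation_matrix(traces: TraceSet | np.ndarray) -> pd.DataFrame:
    """Pearson correlation at lag zero over jointly valid frames.

    Rows/columns are identity ids.  A constant trace has no defined
    correlation; its row and column are NaN (logged).
    """
    if isinstance(traces, TraceSet):
        df = traces.to_dataframe()
        cols = [c for c in df.columns if c.startswith("cell_")]
        data = df[cols]
        ids = [int(c.split("_", 1)[1]) for c in cols]
    else:
        arr = np.asarray(traces, dtype=float)
        data = pd.DataFrame(arr.T)
        ids = list(range(arr.shape[0]))
    if data.shape[1] < 2:
        raise ValueError("need at least 2 identities")
    corr = data.corr()  # pairwise-complete, Pearson
    corr.index = ids
    corr.columns = ids
    for ident in ids:
        if np.isnan(corr.loc[ident].drop(ident)).all():
            logger.warning("correlation_matrix: trace %s is constant", ident)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def dendrogram_order(corr_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Leaf order from Ward-linkage clustering of correlation rows.

    Distances are pairwise Manhattan (city-block) distances between the rows
    of the correlation matrix; the returned permutation sorts the matrix the
    way its dendrogram displays it.
    """
    arr = np.asarray(corr_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("need a square correlation matrix")
    if arr.shape[0] == 1:
        return np.array([0])
    dists = pdist(arr, metric="cityblock")
    tree = linkage(dists, method="ward")
    return np.asarray(leaves_list(tree))


def gaussian_smooth(trace: np.ndarray, sigma_frames: float = 1.0) -> np.ndarray:
    """Convolve with a normalised Gaussian kernel (preserves the mean)."""
    return gaussian_filter1d(np.asarray(trace, dtype=float), sigma=sigma_frames, mode="reflect")


def evaluate_online_run(
    detection_sets: Sequence[DetectionSet],
    gt_boxes: Sequence[BoundingBox] | Sequence[Sequence[BoundingBox]],
    n_frames: Optional[int] = None,
    per_frame_gt: bool = False,
    overlap_cutoff: float = 0.5,
) -> pd.DataFrame:
    """F-1 against ground truth at each detection emission.

    ``gt_boxes`` is either one static box set or, when motion was injected,
    one set per frame (``per_frame_gt=True``); the emission's frame index
    selects the set.  Returns a DataFrame with the run fraction (emission
    frame / total frames), precision, recall, and F-1 per emission.
    """
    if n_frames is None:
        n_frames = max((d.frame_index for d in detection_sets), default=0) + 1
    rows = []
    for det in detection_sets:
        gt = gt_boxes[det.frame_index] if per_frame_gt else gt_boxes
        report = match_detections(det.boxes, list(gt), overlap_cutoff=overlap_cutoff)
        rows.append(
            {
                "frame": det.frame_index,
                "fraction": (det.frame_index + 1) / n_frames,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
            }
        )
    return pd.DataFrame(rows)
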