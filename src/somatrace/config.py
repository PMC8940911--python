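"""Pipeline configuration: one validated object aggregating every stage's knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the detection/tracking/extraction pipeline.

    Defaults follow the reference operating point: percentile window 80–95,
    duplicate/new-identity overlap 0.2 (area-sum measure), match cutoff
    0.5, tiles of 128 px with 28 px overlap, Savitzky–Golay window 15 with
    peak prominence 7 and minimum height 3.
    """

    # frame downsampling
    mode: str = "sliding"  # sliding | step
    n_frames: int = 10  # buffer length n
    # detector input
    upscale_factor: Optional[float] = 1.0  # None -> heuristic ("auto")
    register: bool = False
    max_shift: float = 13.0
    # detector
    detector: str = "reference"  # reference | cnn
    model_path: Optional[str] = None
    score_threshold: float = 0.25
    nms_threshold: float = 0.2
    # tracking
    new_id_threshold: float = 0.2
    matching: str = "greedy"  # greedy | optimal
    # segmentation / extraction
    p_low: float = 80.0
    p_high: float = 95.0
    background: str = "global"  # global | local
    extract_inactive: bool = True
    shift_inactive: bool = True  # rigid-shift inactive boxes (vs freeze)
    # tiling (mesoscopic)
    tile_size: int = 128
    tile_overlap: int = 28
    batch_size: int = 8
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("sliding", "step"):
            raise ValueError(f"mode must be sliding|step, got {self.mode!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.upscale_factor is not None and self.upscale_factor <= 0:
            raise ValueError("upscale_factor must be positive (or None for auto)")
        if not (0 <= self.score_threshold <= 1):
            raise ValueError("score_threshold must lie in [0, 1]")
        if not (0 <= self.p_low < self.p_high <= 100):
            raise ValueError("need 0 <= p_low < p_high <= 100")
        if self.background not in ("global", "local"):
            raise ValueError("background must be global|local")
        if self.tile_overlap >= self.tile_size:
            raise ValueError("tile_overlap must be smaller than tile_size")
        if self.detector not in ("reference", "cnn"):
            raise ValueError("detector must be reference|cnn")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if data.get("upscale_factor") == "auto":
            data = dict(data, upscale_factor=None)
        return cls(**data)
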