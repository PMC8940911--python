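"""Per-identity fluorescence traces plus the global background series.

A trace is undefined (NaN) before the first frame at which its identity was
detected: extraction starts only once a cell exists in the registry, so the
prefix is genuinely missing data, never zero.  The background series ``bg``
is defined for every processed frame.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["TraceSet"]


class TraceSet:
    """Aligned per-identity fluorescence series and the background trace."""

    def __init__(self, frame_rate: float = 1.0):
        if frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.frame_rate = float(frame_rate)
        self._traces: Dict[int, list] = {}
        self._bg: list = []
        self.first_valid: Dict[int, int] = {}

    # -- construction -----------------------------------------------------
    def append_frame(self, bg_value: float, values: Mapping[int, float]) -> None:
        """Record one frame: the background value plus one value per identity.

        Identities seen for the first time get a NaN prefix covering all
        earlier frames.  Identities known to the set but absent from
        ``values`` (e.g. a failed segmentation) get NaN for this frame.
        """
        t = len(self._bg)
        self._bg.append(float(bg_value))
        for ident, value in values.items():
            if ident not in self._traces:
                self._traces[ident] = [np.nan] * t
                self.first_valid[ident] = t
            self._traces[ident].append(float(value))
        for ident, series in self._traces.items():
            if len(series) < t + 1:
                series.append(np.nan)

    # -- access -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self._bg)

    @property
    def identities(self) -> list[int]:
        return sorted(self._traces)

    @property
    def bg(self) -> np.ndarray:
        return np.asarray(self._bg, dtype=float)

    def trace(self, identity: int) -> np.ndarray:
        return np.asarray(self._traces[identity], dtype=float)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) / self.frame_rate

    def __contains__(self, identity: int) -> bool:
        return identity in self._traces

    def __len__(self) -> int:
        return len(self._traces)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraceSet):
            return NotImplemented
        if self.identities != other.identities or self.n_frames != other.n_frames:
            return False
        if not np.array_equal(self.bg, other.bg):
            return False
        for ident in self.identities:
            a, b = self.trace(ident), other.trace(ident)
            if not np.array_equal(a, b, equal_nan=True):
                return False
        return True

    # -- tabular round-trip -------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """One row per frame: frame index, timestamp, bg, one column per cell."""
        data = {
            "frame": np.arange(self.n_frames, dtype=int),
            "time_s": self.times(),
            "bg": self.bg,
        }
        for ident in self.identities:
            data[f"cell_{ident:05d}"] = self.trace(ident)
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate: Optional[float] = None) -> "TraceSet":
        if frame_rate is None:
            if len(df) > 1:
                dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
                frame_rate = 1.0 / dt if dt > 0 else 1.0
            else:
                frame_rate = 1.0
        ts = cls(frame_rate=frame_rate)
        ts._bg = [float(v) for v in df["bg"].to_numpy()]
        for col in df.columns:
            if not col.startswith("cell_"):
                continue
            ident = int(col.split("_", 1)[1])
            series = df[col].to_numpy(dtype=float)
            ts._traces[ident] = list(series)
            valid = np.flatnonzero(~np.isnan(series))
            ts.first_valid[ident] = int(valid[0]) if valid.size else 0
        return ts

    @classmethod
    def from_arrays(
        cls,
        traces: Mapping[int, Iterable[float]],
        bg: Iterable[float],
        frame_rate: float = 1.0,
    ) -> "TraceSet":
        ts = cls(frame_rate=frame_rate)
        ts._bg = [float(v) for v in bg]
        for ident, series in traces.items():
            arr = np.asarray(list(series), dtype=float)
            if arr.size != ts.n_frames:
                raise ValueError(
                    f"trace {ident} has {arr.size} samples, expected {ts.n_frames}"
                )
            ts._traces[int(ident)] = list(arr)
            valid = np.flatnonzero(~np.isnan(arr))
            ts.first_valid[int(ident)] = int(valid[0]) if valid.size else 0
        return ts
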