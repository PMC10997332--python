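"""The per-recording container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

CONDITIONS = ("closed", "open", "dark", "grating")
TREATMENTS = ("naive", "drug", "saline")


def empty_marker_table() -> pd.DataFrame:
    return pd.DataFrame({"time_s": pd.Series(dtype=float),
                         "type": pd.Series(dtype=object)})


@dataclass
class Session:
    """One 5-minute recording.

    ``traces`` is an (n_roi, n_samples) array, raw fluorescence or dF/F
    fraction depending on ``traces_kind``.  ``speed`` and ``flow`` are the
    locomotion and visual-flow speed traces in cm/s on the same time base.
    ``markers`` records stimulus events injected or logged at acquisition
    (mismatch halts, grating onsets) as a (time_s, type) table.
    """

    traces: np.ndarray
    roi_ids: list[str]
    speed: np.ndarray
    flow: np.ndarray
    fs_hz: float
    mouse_id: str
    session_id: str
    condition: str
    treatment: str = "naive"
    indicator: str = "gcamp"
    genotype: str = ""
    traces_kind: str = "dff"  # "raw" or "dff"
    detrended: bool = False
    markers: pd.DataFrame = field(default_factory=empty_marker_table)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (n_roi, n_samples)")
        if self.traces.shape[0] != len(self.roi_ids):
            raise ValueError("traces row count does not match roi_ids")
        n = self.traces.shape[1]
        for name, arr in (("speed", self.speed), ("flow", self.flow)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} does not match "
                                 f"traces length {n}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; "
                             f"expected one of {CONDITIONS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; "
                             f"expected one of {TREATMENTS}")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def trace(self, roi_id: str) -> np.ndarray:
        return self.traces[self.roi_ids.index(roi_id)]

    def with_traces(self, traces: np.ndarray, **changes: Any) -> "Session":
        return replace(self, traces=traces, **changes)

    def copy(self) -> "Session":
        return replace(
            self,
            traces=self.traces.copy(),
            speed=self.speed.copy(),
            flow=self.flow.copy(),
            markers=self.markers.copy(),
            meta=dict(self.meta),
        )
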