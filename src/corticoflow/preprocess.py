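"""Fluorescence preprocessing: dF/F, drift correction, session QC.

dF/F uses the median fluorescence of the whole recording as F0.  Slow
drift (e.g. thermal brightening of the excitation LED) is removed by
subtracting a running low-percentile baseline: the 8th percentile of a
62.5 s moving window by default (15 s is the conventional choice for
two-photon data).  The window is centred and truncated at the session
edges; a centred window avoids the phase lag a trailing window would
introduce into onset-locked averages.  The percentile is the
linear-interpolation quantile, so a naive per-sample reimplementation
reproduces the output bit-exactly.

Sessions in which the across-ROI mean dF/F stays above 30% for more than
10 s (strictly) are excluded as seizure-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .session import Session


@dataclass
class FluorescenceTrace:
    """Raw fluorescence of one ROI, arbitrary units."""

    values: np.ndarray
    fs_hz: float
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite fluorescence in ROI {self.roi_id!r}")


@dataclass
class DffTrace:
    """dF/F of one ROI as a dimensionless fraction (x100 for percent)."""

    values: np.ndarray
    fs_hz: float
    roi_id: str = ""
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")


def dff(raw: np.ndarray) -> np.ndarray:
    """(F - F0) / F0 with F0 the median of the whole recording."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("raw trace must be 1-D with more than one sample")
    f0 = float(np.median(raw))
    if f0 <= 0:
        raise ValueError("nonpositive baseline")
    return (raw - f0) / f0


def compute_dff(raw: FluorescenceTrace) -> DffTrace:
    return DffTrace(values=dff(raw.values), fs_hz=raw.fs_hz, roi_id=raw.roi_id)


def running_percentile(values: np.ndarray, window: int,
                       percentile: float) -> np.ndarray:
    """Centred moving-window percentile with edge truncation.

    For an even window the centre is placed so that (window-1)//2 samples
    precede and window//2 follow the current sample.  Quantiles use
    numpy's linear-interpolation definition.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if window > n:
        raise ValueError(f"window ({window} samples) longer than trace ({n})")
    hl = (window - 1) // 2
    hr = window // 2
    baseline = np.empty(n)
    # interior: fully populated windows, vectorised in chunks
    lo, hi = hl, n - hr  # samples whose window is complete
    if hi > lo:
        view = np.lib.stride_tricks.sliding_window_view(values, window)
        # cap chunk memory at ~64 MB
        chunk = max(1, int(8e6 // max(window, 1)))
        for start in range(lo, hi, chunk):
            stop = min(start + chunk, hi)
            baseline[start:stop] = np.quantile(
                view[start - hl:stop - hl], percentile, axis=1)
    # truncated edges
    for i in range(0, min(lo, n)):
        baseline[i] = np.quantile(values[:i + hr + 1], percentile)
    for i in range(max(hi, 0), n):
        baseline[i] = np.quantile(values[i - hl:], percentile)
    return baseline


def detrend(values: np.ndarray, fs_hz: float, window_s: float = 62.5,
            percentile: float = 0.08) -> np.ndarray:
    """Subtract the running low-percentile baseline from a dF/F trace."""
    window = int(round(window_s * fs_hz))
    return values - running_percentile(values, window, percentile)


def percentile_detrend(trace: DffTrace, window_s: float = 62.5,
                       percentile: float = 0.08) -> DffTrace:
    out = detrend(trace.values, trace.fs_hz, window_s, percentile)
    return replace(trace, values=out, detrended=True)


def preprocess_session(session: Session, do_detrend: bool = True,
                       window_s: float = 62.5,
                       percentile: float = 0.08) -> Session:
    """Raw-fluorescence session -> drift-corrected dF/F session.

    Sessions already carrying dF/F (``traces_kind == 'dff'``) skip the
    dF/F step but are still detrended when requested.
    """
    traces = session.traces
    if session.traces_kind == "raw":
        traces = np.vstack([dff(row) for row in traces])
    if do_detrend:
        traces = np.vstack([
            detrend(row, session.fs_hz, window_s, percentile)
            for row in traces
        ])
    return session.with_traces(traces, traces_kind="dff",
                               detrended=bool(do_detrend or session.detrended))


def _elevated_windows(mean_trace: np.ndarray, fs_hz: float, level: float,
                      min_duration_s: float) -> list[tuple[float, float]]:
    """Windows (start_s, end_s) where the trace stays strictly above
    ``level`` for strictly more than ``min_duration_s``."""
    above = mean_trace > level
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    out = []
    for s, e in zip(starts, ends):
        duration = (e - s) / fs_hz
        if duration > min_duration_s:
            out.append((s / fs_hz, e / fs_hz))
    return out


def qc_exclude_sessions(
    sessions: Sequence[Session],
    level: float = 0.30,
    min_duration_s: float = 10.0,
    required_rois: Sequence[str] | None = None,
) -> tuple[list[Session], list[Session], pd.DataFrame]:
    """Drop seizure-like sessions.

    A session is excluded iff the mean dF/F across all its ROIs stays
    above ``level`` continuously for strictly more than ``min_duration_s``
    seconds.  Returns (kept, excluded, report); the report lists every
    offending window.
    """
    kept: list[Session] = []
    excluded: list[Session] = []
    rows = []
    for session in sessions:
        if required_rois is not None:
            missing = [r for r in required_rois if r not in session.roi_ids]
            if missing:
                raise ValueError(
                    f"session {session.session_id!r} is missing ROI(s) "
                    f"{missing}")
        mean_trace = session.traces.mean(axis=0)
        windows = _elevated_windows(mean_trace, session.fs_hz, level,
                                    min_duration_s)
        is_excluded = bool(windows)
        (excluded if is_excluded else kept).append(session)
        rows.append({
            "session_id": session.session_id,
            "mouse_id": session.mouse_id,
            "excluded": is_excluded,
            "n_offending_windows": len(windows),
            "first_offending_window_s": windows[0][0] if windows else np.nan,
            "offending_windows": windows,
        })
    report = pd.DataFrame(rows)
    return kept, excluded, report
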