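"""Onset detection, alignment, baselining and event-triggered averages.

Locomotion (or visual-flow) onsets are upward crossings of a 30 cm/s
speed threshold.  To keep only well-isolated onsets, a candidate is valid
iff neither the locomotion nor the visual-flow trace rises above a
quiescence level (1 cm/s) anywhere in the exclusion window (3 s; 1 s for
eGFP data) preceding the crossing.  Onset time is the first sample at or
above threshold — at 10 ms bins sub-sample timing is irrelevant.
Candidates whose exclusion window (or alignment window) extends beyond
the session bounds are dropped rather than zero-padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import BASELINE_WINDOWS
from .session import Session
from . import stats as cf_stats

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["time_s", "type", "valid", "exclusion_reason"]


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": pd.Series(dtype=float),
        "type": pd.Series(dtype=object),
        "valid": pd.Series(dtype=bool),
        "exclusion_reason": pd.Series(dtype=object),
    })


def detect_onsets(
    primary_speed: np.ndarray,
    other_speed: np.ndarray,
    fs_hz: float,
    threshold_cms: float = 30.0,
    exclusion_window_s: float = 3.0,
    quiescence_cms: float = 1.0,
    onset_type: str = "loco_closed",
) -> pd.DataFrame:
    """Threshold-crossing onsets on ``primary_speed`` gated by quiescence.

    Candidates are samples where the primary trace crosses from below to
    at-or-above ``threshold_cms``.  A candidate is valid iff neither
    trace exceeds ``quiescence_cms`` at any sample of the
    ``exclusion_window_s`` preceding it; candidates whose window starts
    before the recording are invalid ("pre-window out of bounds").  For
    visual-flow onsets pass the flow trace as ``primary_speed`` and the
    locomotion trace as ``other_speed`` — the symmetric quiescence check
    then enforces that the mouse was not locomoting before the onset.
    """
    primary = np.asarray(primary_speed, dtype=float)
    other = np.asarray(other_speed, dtype=float)
    if primary.shape != other.shape:
        raise ValueError(
            f"trace lengths differ: {primary.shape} vs {other.shape}")
    above = primary >= threshold_cms
    crossing = above & ~np.concatenate(([True], above[:-1]))
    # a trace that starts at/above threshold has no upward crossing there
    candidates = np.flatnonzero(crossing)
    w = int(round(exclusion_window_s * fs_hz))
    rows = []
    for i in candidates:
        if i - w < 0:
            valid, reason = False, "pre-window out of bounds"
        elif (primary[i - w:i] > quiescence_cms).any() or \
                (other[i - w:i] > quiescence_cms).any():
            valid, reason = False, "activity in pre-window"
        else:
            valid, reason = True, ""
        rows.append({"time_s": i / fs_hz, "type": onset_type,
                     "valid": valid, "exclusion_reason": reason})
    if not rows:
        return empty_event_table()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_session_onsets(
    session: Session,
    threshold_cms: float = 30.0,
    exclusion_window_s: float = 3.0,
    quiescence_cms: float = 1.0,
    include_flow_onsets: bool = True,
) -> pd.DataFrame:
    """Locomotion onsets (and, in open loop, visual-flow onsets) plus the
    session's recorded stimulus markers, as one sorted event table."""
    loco_type = {"closed": "loco_closed", "open": "loco_open"}.get(
        session.condition, "loco_" + session.condition)
    tables = [detect_onsets(session.speed, session.flow, session.fs_hz,
                            threshold_cms, exclusion_window_s,
                            quiescence_cms, onset_type=loco_type)]
    if session.condition == "open" and include_flow_onsets:
        tables.append(detect_onsets(session.flow, session.speed,
                                    session.fs_hz, threshold_cms,
                                    exclusion_window_s, quiescence_cms,
                                    onset_type="flow_open"))
    if len(session.markers):
        tables.append(pd.DataFrame({
            "time_s": session.markers["time_s"].to_numpy(dtype=float),
            "type": session.markers["type"],
            "valid": True,
            "exclusion_reason": "",
        }, columns=EVENT_COLUMNS))
    events = pd.concat(tables, ignore_index=True)
    return events.sort_values("time_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignedResponses:
    """Per-onset snippets: tensor (n_onsets, n_roi, n_bins) at native bins."""

    data: np.ndarray
    roi_ids: list[str]
    window_s: tuple[float, float]
    bin_s: float
    mouse_labels: np.ndarray  # one mouse id per onset
    onset_times_s: np.ndarray
    baselined: bool = False
    baseline_window_s: tuple[float, float] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mouse_labels = np.asarray(self.mouse_labels)
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)

    @property
    def n_onsets(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    @property
    def time_s(self) -> np.ndarray:
        """Onset-relative time of each bin (bin start)."""
        pre = self.window_s[0]
        return pre + np.arange(self.n_bins) * self.bin_s

    def concat(self, other: "AlignedResponses") -> "AlignedResponses":
        if self.roi_ids != other.roi_ids or self.n_bins != other.n_bins:
            raise ValueError("incompatible aligned tensors")
        return replace(
            self,
            data=np.concatenate([self.data, other.data]),
            mouse_labels=np.concatenate([self.mouse_labels,
                                         other.mouse_labels]),
            onset_times_s=np.concatenate([self.onset_times_s,
                                          other.onset_times_s]),
            n_dropped=self.n_dropped + other.n_dropped,
        )


def extract_aligned(
    session: Session,
    events: pd.DataFrame,
    window_s: tuple[float, float] = (-5.0, 3.0),
    event_types: Sequence[str] | None = None,
) -> AlignedResponses:
    """Cut per-onset snippets of all ROI traces around the valid events.

    Events whose window would cross the session bounds are dropped with a
    logged count.  Zero usable events yields an empty tensor (plus a
    warning in the log), not an error.
    """
    pre, post = window_s
    if pre >= post:
        raise ValueError("window start must precede window end")
    fs = session.fs_hz
    i_pre = int(round(pre * fs))
    i_post = int(round(post * fs))
    n_bins = i_post - i_pre
    n = session.n_samples
    use = events[events["valid"].astype(bool)]
    if event_types is not None:
        use = use[use["type"].isin(event_types)]
    snippets, times = [], []
    dropped = 0
    for t in use["time_s"].to_numpy(dtype=float):
        j = int(round(t * fs))
        lo, hi = j + i_pre, j + i_post
        if lo < 0 or hi > n:
            dropped += 1
            continue
        snippets.append(session.traces[:, lo:hi])
        times.append(t)
    if dropped:
        logger.info("extract_aligned: dropped %d event(s) with windows "
                    "outside session %s", dropped, session.session_id)
    if not snippets:
        logger.warning("extract_aligned: no usable events in session %s",
                       session.session_id)
        data = np.empty((0, len(session.roi_ids), n_bins))
    else:
        data = np.stack(snippets)
    return AlignedResponses(
        data=data, roi_ids=list(session.roi_ids), window_s=(pre, post),
        bin_s=1.0 / fs,
        mouse_labels=np.array([session.mouse_id] * len(times), dtype=object),
        onset_times_s=np.array(times), n_dropped=dropped)


def collect_aligned(
    sessions: Sequence[Session],
    window_s: tuple[float, float] = (-5.0, 3.0),
    event_types: Sequence[str] | None = None,
    detector_kwargs: dict | None = None,
) -> AlignedResponses:
    """Detect onsets in each session and pool the aligned snippets."""
    detector_kwargs = detector_kwargs or {}
    pooled: AlignedResponses | None = None
    for session in sessions:
        events = detect_session_onsets(session, **detector_kwargs)
        aligned = extract_aligned(session, events, window_s=window_s,
                                  event_types=event_types)
        pooled = aligned if pooled is None else pooled.concat(aligned)
    if pooled is None:
        raise ValueError("no sessions supplied")
    return pooled


def baseline_subtract(aligned: AlignedResponses,
                      mode: str = "onset_gcamp") -> AlignedResponses:
    """Subtract the per-onset, per-ROI mean over the mode's window.

    Modes: 'stimulus' (-200..0 ms, unpredictable stimuli), 'onset_gcamp'
    (-2900..-2700 ms) and 'onset_egfp' (-900..-700 ms) for locomotion and
    flow onsets.  After subtraction the baseline-window mean is exactly
    zero for every onset and ROI; the operation is idempotent.
    """
    if mode not in BASELINE_WINDOWS:
        raise ValueError(f"unknown baseline mode {mode!r}; "
                         f"expected one of {sorted(BASELINE_WINDOWS)}")
    start, end = BASELINE_WINDOWS[mode]
    t = aligned.time_s
    if start < t[0] - 1e-9 or end > aligned.window_s[1] + 1e-9:
        raise ValueError(
            f"baseline window {BASELINE_WINDOWS[mode]} s for mode {mode!r} "
            f"lies outside the aligned window {aligned.window_s} s")
    mask = (t >= start - 1e-9) & (t < end - 1e-9)
    if not mask.any():
        raise ValueError(
            f"baseline window {BASELINE_WINDOWS[mode]} s for mode {mode!r} "
            "contains no bins")
    base = aligned.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(aligned, data=aligned.data - base, baselined=True,
                   baseline_window_s=(start, end))


# ---------------------------------------------------------------------------
# triggered averages


@dataclass
class TriggeredResponse:
    """Event-triggered mean per ROI with an uncertainty band.

    ``band`` records how the interval was computed: 'hboot' for the
    hierarchical-bootstrap quantile band, 'boot' for the single-mouse
    onset-level fallback, 'sem' for mean +/- SEM over mice.
    """

    mean: np.ndarray      # (n_roi, n_bins)
    ci_low: np.ndarray
    ci_high: np.ndarray
    roi_ids: list[str]
    time_s: np.ndarray
    n_onsets: int
    n_mice: int
    band: str = "hboot"
    ci: float = 0.90
    mouse_ids: list[str] = field(default_factory=list)
    per_mouse: np.ndarray | None = None  # (n_mice, n_roi, n_bins)

    def roi(self, roi_id: str) -> np.ndarray:
        return self.mean[self.roi_ids.index(roi_id)]


def triggered_average(
    aligned: AlignedResponses,
    n_boot: int = 1000,
    ci: float = 0.90,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    share_indices: bool = True,
) -> TriggeredResponse:
    """Mean over pooled onsets with a per-bin hierarchical-bootstrap band
    (resampling mice, then onsets).  With a single mouse the band
    degrades to an onset-level bootstrap, with a logged warning."""
    if aligned.n_onsets == 0:
        raise ValueError("no onsets to average")
    rng = rng if rng is not None else np.random.default_rng(seed)
    mice = list(dict.fromkeys(aligned.mouse_labels.tolist()))
    labels = aligned.mouse_labels
    if len(mice) == 1:
        logger.warning("triggered_average: single mouse — falling back to "
                       "an onset-level bootstrap band")
        labels = np.arange(aligned.n_onsets)  # every onset its own "mouse"
        band = "boot"
    else:
        band = "hboot"
    mean, lo, hi = cf_stats.hboot_timecourse(
        aligned.data, labels, n_boot=n_boot, ci=ci, rng=rng,
        share_indices=share_indices)
    per_mouse = np.stack([
        aligned.data[aligned.mouse_labels == m].mean(axis=0) for m in mice])
    return TriggeredResponse(
        mean=mean, ci_low=lo, ci_high=hi, roi_ids=list(aligned.roi_ids),
        time_s=aligned.time_s, n_onsets=aligned.n_onsets, n_mice=len(mice),
        band=band, ci=ci, mouse_ids=list(mice), per_mouse=per_mouse)


def linear_sum(resp_a: TriggeredResponse,
               resp_b: TriggeredResponse) -> TriggeredResponse:
    """Per-mouse sum of two responses: average each response within each
    mouse, sum the two per-mouse means, then report the across-mouse mean
    with an SEM band (band='sem')."""
    if resp_a.roi_ids != resp_b.roi_ids:
        raise ValueError("ROI sets differ between responses")
    if resp_a.mean.shape != resp_b.mean.shape:
        raise ValueError("window/bin layouts differ between responses")
    if resp_a.per_mouse is None or resp_b.per_mouse is None:
        raise ValueError("per-mouse means required (use triggered_average)")
    if set(resp_a.mouse_ids) != set(resp_b.mouse_ids):
        only_a = sorted(set(resp_a.mouse_ids) - set(resp_b.mouse_ids))
        only_b = sorted(set(resp_b.mouse_ids) - set(resp_a.mouse_ids))
        raise ValueError(f"mouse sets differ: only in a: {only_a}, "
                         f"only in b: {only_b}")
    order = resp_a.mouse_ids
    idx_b = [resp_b.mouse_ids.index(m) for m in order]
    sums = resp_a.per_mouse + resp_b.per_mouse[idx_b]
    n_mice = len(order)
    mean = sums.mean(axis=0)
    if n_mice > 1:
        sem = sums.std(axis=0, ddof=1) / np.sqrt(n_mice)
    else:
        sem = np.zeros_like(mean)
    return TriggeredResponse(
        mean=mean, ci_low=mean - sem, ci_high=mean + sem,
        roi_ids=list(resp_a.roi_ids), time_s=resp_a.time_s,
        n_onsets=resp_a.n_onsets + resp_b.n_onsets, n_mice=n_mice,
        band="sem", ci=float("nan"), mouse_ids=list(order), per_mouse=sums)


def response_map(
    movie: np.ndarray,
    events: pd.DataFrame,
    fs_hz: float,
    avg_window_s: tuple[float, float] = (0.0, 1.0),
    baseline_window_s: tuple[float, float] = (-0.2, 0.0),
) -> np.ndarray:
    """Per-pixel baseline-subtracted mean response over a post-onset window.

    ``movie`` is (n_frames, height, width) on the events' time base.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (n_frames, height, width)")
    use = events[events["valid"].astype(bool)]
    times = use["time_s"].to_numpy(dtype=float)
    if times.size == 0:
        raise ValueError("no valid events for response map")
    n = movie.shape[0]
    b0, b1 = (int(round(s * fs_hz)) for s in baseline_window_s)
    a0, a1 = (int(round(s * fs_hz)) for s in avg_window_s)
    maps = []
    for t in times:
        j = int(round(t * fs_hz))
        if j + min(b0, a0) < 0 or j + max(b1, a1) > n:
            continue
        baseline = movie[j + b0:j + b1].mean(axis=0)
        maps.append(movie[j + a0:j + a1].mean(axis=0) - baseline)
    if not maps:
        raise ValueError("no events with complete windows for response map")
    return np.mean(maps, axis=0)
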