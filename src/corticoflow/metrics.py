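"""Headline statistics: closed/open similarity, speed-activity
correlation, distance-resolved pairwise ROI correlation, density maps and
drug-induced correlation change.

Pairwise correlations are Pearson coefficients over whole 5-minute
sessions for all 66 pairs of the 12 ROIs, with pair distances normalised
by the animal's bregma-lambda distance.  Pairs are split into short- and
long-range at 0.9 bregma-lambda units (the boundary itself counts as
long-range).  The drug effect per (mouse, pair) is the correlation change
after versus before treatment, normalised to the value before.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .events import TriggeredResponse
from .geometry import RoiGeometry
from .session import Session

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["mouse", "session", "roi_a", "roi_b", "r", "d_norm"]


# ---------------------------------------------------------------------------
# closed/open-loop similarity


def boxcar_smooth(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Centred moving average with edge truncation (unbiased at edges)."""
    if n_bins <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n_bins)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


@dataclass
class SimilarityResult:
    per_roi: pd.Series     # Pearson r per ROI (NaN where undefined)
    mean: float            # across-ROI mean
    sem: float             # SEM over the ROIs
    window_s: tuple[float, float]
    smooth_s: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def onset_similarity(
    closed_avg: TriggeredResponse,
    open_avg: TriggeredResponse,
    window_s: tuple[float, float] = (-5.0, 3.0),
    smooth_s: float = 1.0,
) -> SimilarityResult:
    """Correlation between the averaged closed- and open-loop onset
    responses (1 s moving average, -5 s to +3 s window), per ROI, with
    mean +/- SEM across the ROIs as the summary."""
    if closed_avg.roi_ids != open_avg.roi_ids:
        raise ValueError("ROI sets differ")
    if closed_avg.mean.shape != open_avg.mean.shape:
        raise ValueError("bin layouts differ")
    t = closed_avg.time_s
    mask = (t >= window_s[0] - 1e-9) & (t < window_s[1] - 1e-9)
    bin_s = float(t[1] - t[0]) if t.size > 1 else 1.0
    n_smooth = max(1, int(round(smooth_s / bin_s)))
    values = {}
    for i, roi in enumerate(closed_avg.roi_ids):
        a = boxcar_smooth(closed_avg.mean[i], n_smooth)[mask]
        b = boxcar_smooth(open_avg.mean[i], n_smooth)[mask]
        r = _pearson(a, b)
        if np.isnan(r):
            logger.warning("onset_similarity: zero-variance trace for ROI "
                           "%s — similarity undefined", roi)
        values[roi] = r
    per_roi = pd.Series(values)
    finite = per_roi.dropna()
    mean = float(finite.mean()) if len(finite) else float("nan")
    sem = (float(finite.std(ddof=1) / np.sqrt(len(finite)))
           if len(finite) > 1 else float("nan"))
    return SimilarityResult(per_roi=per_roi, mean=mean, sem=sem,
                            window_s=window_s, smooth_s=smooth_s)


def per_mouse_v1_similarity(
    mouse_avgs: Mapping[str, Mapping[str, TriggeredResponse]],
    min_resp: float = 0.01,
    window_s: tuple[float, float] = (-5.0, 3.0),
    smooth_s: float = 1.0,
    v1_rois: tuple[str, str] = ("V1_L", "V1_R"),
) -> pd.DataFrame:
    """Per-mouse closed/open similarity of V1 onset responses.

    ``mouse_avgs[mouse]['closed' | 'open']`` are triggered averages with
    both V1 ROIs present.  Per hemisphere the correlation of the two
    condition averages is computed as in :func:`onset_similarity`; the
    two hemisphere coefficients are averaged to one value per mouse.
    Mice whose peak |response| is below ``min_resp`` (dF/F fraction) in
    either condition are excluded with a reason, as are mice lacking
    onsets in a condition.
    """
    rows = []
    for mouse, conds in mouse_avgs.items():
        row = {"mouse": mouse, "r_left": np.nan, "r_right": np.nan,
               "r": np.nan, "excluded": False, "reason": ""}
        if "closed" not in conds or "open" not in conds:
            missing = sorted({"closed", "open"} - set(conds))
            row.update(excluded=True, reason=f"no onsets in {missing}")
            rows.append(row)
            continue
        closed, opened = conds["closed"], conds["open"]
        t = closed.time_s
        mask = (t >= window_s[0] - 1e-9) & (t < window_s[1] - 1e-9)
        bin_s = float(t[1] - t[0]) if t.size > 1 else 1.0
        n_smooth = max(1, int(round(smooth_s / bin_s)))
        peaks = {}
        rs = {}
        for hemi, roi in zip(("left", "right"), v1_rois):
            a = boxcar_smooth(closed.roi(roi), n_smooth)[mask]
            b = boxcar_smooth(opened.roi(roi), n_smooth)[mask]
            rs[hemi] = _pearson(a, b)
            peaks.setdefault("closed", []).append(np.abs(a).max())
            peaks.setdefault("open", []).append(np.abs(b).max())
        weak = [c for c in ("closed", "open")
                if max(peaks[c]) < min_resp]
        row["r_left"], row["r_right"] = rs["left"], rs["right"]
        row["r"] = float(np.nanmean([rs["left"], rs["right"]]))
        if weak:
            row.update(excluded=True,
                       reason=f"response below {min_resp:g} dF/F in {weak}")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# speed-activity correlation


def speed_activity_correlation(session: Session) -> pd.Series:
    """Pearson r between each ROI's activity and locomotion speed over the
    whole session.  A session in which the mouse never moved (constant
    speed) yields NaN for every ROI, with a warning."""
    speed = session.speed
    if speed.std() == 0:
        logger.warning("speed_activity_correlation: constant speed in "
                       "session %s — correlation undefined",
                       session.session_id)
        return pd.Series(np.nan, index=session.roi_ids)
    values = {}
    for roi, trace in zip(session.roi_ids, session.traces):
        values[roi] = _pearson(trace, speed)
    return pd.Series(values)


def speed_activity_map(session: Session, movie: np.ndarray) -> np.ndarray:
    """Per-pixel correlation between a (n_frames, h, w) movie and speed."""
    movie = np.asarray(movie, dtype=float)
    speed = session.speed
    if movie.shape[0] != speed.size:
        raise ValueError("movie and speed share no time base")
    s = (speed - speed.mean())
    sd = s.std()
    if sd == 0:
        return np.full(movie.shape[1:], np.nan)
    flat = movie.reshape(movie.shape[0], -1)
    f = flat - flat.mean(axis=0)
    denom = f.std(axis=0) * sd * movie.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (f * s[:, None]).sum(axis=0) / denom
    return r.reshape(movie.shape[1:])


def aggregate_speed_correlation(
    per_session: pd.DataFrame,
) -> pd.DataFrame:
    """Average per-session coefficients to one value per mouse, ROI and
    condition.  Input columns: mouse, session, condition, roi, r."""
    return (per_session
            .groupby(["mouse", "condition", "roi"], sort=True)["r"]
            .mean().reset_index())


def speed_correlation_difference(after: pd.DataFrame,
                                 before: pd.DataFrame) -> pd.DataFrame:
    """after - before treatment difference of mouse x ROI x condition
    averages (outputs of :func:`aggregate_speed_correlation`)."""
    keys = ["mouse", "condition", "roi"]
    merged = after.merge(before, on=keys, suffixes=("_after", "_before"))
    merged["dr"] = merged["r_after"] - merged["r_before"]
    return merged[keys + ["r_before", "r_after", "dr"]]


# ---------------------------------------------------------------------------
# pairwise ROI correlations vs distance


def pairwise_roi_correlation(session: Session,
                             geometry: RoiGeometry) -> pd.DataFrame:
    """Pearson r for all unordered ROI pairs over the session, with the
    pair distance in bregma-lambda units.  Pairs involving a
    zero-variance ROI get r = NaN (flagged missing)."""
    traces = {roi: session.trace(roi) for roi in session.roi_ids}
    sds = {roi: traces[roi].std() for roi in session.roi_ids}
    for roi, sd in sds.items():
        if sd == 0:
            logger.warning("pairwise_roi_correlation: zero-variance ROI %s "
                           "in session %s", roi, session.session_id)
    rows = []
    for roi_a, roi_b in combinations(sorted(session.roi_ids), 2):
        if sds[roi_a] == 0 or sds[roi_b] == 0:
            r = float("nan")
        else:
            r = _pearson(traces[roi_a], traces[roi_b])
        rows.append({"mouse": session.mouse_id,
                     "session": session.session_id,
                     "roi_a": roi_a, "roi_b": roi_b, "r": r,
                     "d_norm": geometry.d_norm(roi_a, roi_b)})
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def pair_correlation_cohort(sessions: Sequence[Session],
                            geometry: RoiGeometry) -> pd.DataFrame:
    """Concatenated pair table for many sessions."""
    frames = [pairwise_roi_correlation(s, geometry) for s in sessions]
    return pd.concat(frames, ignore_index=True)


def correlation_matrix(pairs: pd.DataFrame,
                       roi_ids: Sequence[str]) -> np.ndarray:
    """Reassemble a symmetric unit-diagonal matrix from one session's
    pair table (r averaged if multiple rows per pair)."""
    n = len(roi_ids)
    index = {roi: i for i, roi in enumerate(roi_ids)}
    mat = np.eye(n)
    grouped = pairs.groupby(["roi_a", "roi_b"])["r"].mean()
    for (a, b), r in grouped.items():
        mat[index[a], index[b]] = r
        mat[index[b], index[a]] = r
    return mat


# ---------------------------------------------------------------------------
# density maps


@dataclass
class DensityMap:
    """Pair density over (distance, correlation) on a square grid.

    ``grid`` holds raw counts (mass = number of pairs); ``smoothed`` is
    the Gaussian-filtered field renormalised to the same total mass; the
    contour level is half the smoothed peak.
    """

    grid: np.ndarray
    smoothed: np.ndarray
    d_edges: np.ndarray
    r_edges: np.ndarray
    sigma_bins: float
    contour_level: float
    peak_density: float

    @property
    def n_pairs(self) -> float:
        return float(self.grid.sum())


def correlation_distance_density(
    pairs: pd.DataFrame,
    n_bins: int = 40,
    sigma_bins: float = 1.0,
    d_range: tuple[float, float] = (0.0, 1.6),
    r_range: tuple[float, float] = (-0.25, 1.0),
) -> DensityMap:
    """Bin (d_norm, r) pairs on an ``n_bins`` x ``n_bins`` grid and smooth
    with a Gaussian filter.

    Values outside the fixed ranges are clipped into the outermost bins
    so the grid mass always equals the number of finite input pairs.
    Smoothing is renormalised to preserve that mass; the contour level is
    0.5 x the smoothed peak.
    """
    use = pairs.dropna(subset=["r", "d_norm"])
    if not len(use):
        raise ValueError("no pairs to bin")
    d = np.clip(use["d_norm"].to_numpy(dtype=float),
                d_range[0], np.nextafter(d_range[1], -np.inf))
    r = np.clip(use["r"].to_numpy(dtype=float),
                r_range[0], np.nextafter(r_range[1], -np.inf))
    grid, d_edges, r_edges = np.histogram2d(
        d, r, bins=n_bins, range=[d_range, r_range])
    if sigma_bins > 0:
        smoothed = gaussian_filter(grid, sigma=sigma_bins, mode="constant")
        total = smoothed.sum()
        if total > 0:
            smoothed = smoothed * (grid.sum() / total)
    else:
        smoothed = grid.copy()
    peak = float(smoothed.max())
    return DensityMap(grid=grid, smoothed=smoothed, d_edges=d_edges,
                      r_edges=r_edges, sigma_bins=sigma_bins,
                      contour_level=0.5 * peak, peak_density=peak)


# ---------------------------------------------------------------------------
# drug-induced correlation change


@dataclass
class DrugChangeResult:
    """Normalised correlation change split into short and long range."""

    table: pd.DataFrame              # per (mouse, pair)
    cutoff: float
    n_dropped_zero_before: int
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for cls in ("short", "long"):
            vals = self.changes(cls)
            if vals.size == 0:
                rows.append({"range": cls, "n": 0})
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            rows.append({
                "range": cls, "n": int(vals.size), "median": med,
                "q1": q1, "q3": q3, "mean": float(vals.mean()),
                "whisker_low": q1 - 1.5 * iqr,
                "whisker_high": q3 + 1.5 * iqr,
            })
        self.summary = pd.DataFrame(rows)

    def changes(self, range_class: str) -> np.ndarray:
        sel = self.table["range"] == range_class
        return self.table.loc[sel, "change"].to_numpy(dtype=float)


def drug_change(before: pd.DataFrame, after: pd.DataFrame,
                cutoff: float = 0.9) -> DrugChangeResult:
    """Normalised change (r_after - r_before) / r_before per (mouse, pair).

    Session-level coefficients are first averaged within each
    (mouse, pair) on each side.  Pairs with d_norm below ``cutoff`` are
    short-range; at or above it, long-range (the boundary is long).
    Pairs whose before-correlation is exactly zero are dropped (division
    undefined) with a logged count.  All pairs are pooled across mice as
    individual data points; the summary reports median, quartiles, mean
    and 1.5 x IQR whiskers per class.
    """
    keys = ["mouse", "roi_a", "roi_b"]

    def collapse(frame: pd.DataFrame) -> pd.DataFrame:
        return (frame.dropna(subset=["r"])
                .groupby(keys, sort=True)
                .agg(r=("r", "mean"), d_norm=("d_norm", "first"))
                .reset_index())

    b = collapse(before)
    a = collapse(after)
    merged = b.merge(a, on=keys, suffixes=("_before", "_after"))
    zero = merged["r_before"] == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.warning("drug_change: dropped %d pair(s) with zero "
                       "before-correlation", n_zero)
        merged = merged[~zero]
    merged = merged.copy()
    merged["change"] = ((merged["r_after"] - merged["r_before"])
                        / merged["r_before"])
    merged["d_norm"] = merged["d_norm_before"]
    merged["range"] = np.where(merged["d_norm"] < cutoff, "short", "long")
    table = merged[keys + ["d_norm", "r_before", "r_after", "change",
                           "range"]].reset_index(drop=True)
    return DrugChangeResult(table=table, cutoff=cutoff,
                            n_dropped_zero_before=n_zero)
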