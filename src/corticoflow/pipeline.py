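"""End-to-end driver: synth (optional) -> preprocess -> QC -> events ->
averages -> metrics -> stats, with a machine-readable run report.

Every artifact written carries the configuration hash and seed; every
exclusion decision (session, onset, pair) is logged with its reason.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import events as cf_events
from . import io as cf_io
from . import metrics as cf_metrics
from . import preprocess as cf_pre
from . import stats as cf_stats
from . import synth as cf_synth
from .config import PipelineConfig
from .geometry import default_geometry
from .session import Session

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending session."""


def _detector_kwargs(config: PipelineConfig) -> dict[str, float]:
    return dict(threshold_cms=config.onset_threshold_cms,
                exclusion_window_s=config.exclusion_window_s,
                quiescence_cms=config.quiescence_cms)


def mouse_condition_averages(
    sessions: Sequence[Session],
    config: PipelineConfig,
    rng: np.random.Generator,
    event_types: Sequence[str] | None = None,
) -> dict[str, dict[str, cf_events.TriggeredResponse]]:
    """Baseline-subtracted triggered averages per mouse and condition."""
    grouped: dict[tuple[str, str], list[Session]] = {}
    for s in sessions:
        grouped.setdefault((s.mouse_id, s.condition), []).append(s)
    out: dict[str, dict[str, cf_events.TriggeredResponse]] = {}
    for (mouse, condition), group in sorted(grouped.items()):
        types = event_types
        if types is None:
            types = [f"loco_{condition}"]
        aligned = cf_events.collect_aligned(
            group, window_s=config.window_s, event_types=types,
            detector_kwargs=_detector_kwargs(config))
        if aligned.n_onsets == 0:
            logger.warning("no valid onsets for mouse %s condition %s",
                           mouse, condition)
            continue
        aligned = cf_events.baseline_subtract(aligned, config.baseline_mode)
        out.setdefault(mouse, {})[condition] = cf_events.triggered_average(
            aligned, n_boot=config.n_boot_timecourse, ci=config.ci, rng=rng)
    return out


def condition_average(
    sessions: Sequence[Session],
    condition: str,
    config: PipelineConfig,
    rng: np.random.Generator,
    event_types: Sequence[str] | None = None,
) -> cf_events.TriggeredResponse:
    """Cohort-level triggered average for one condition."""
    group = [s for s in sessions if s.condition == condition]
    if not group:
        raise ValueError(f"no sessions with condition {condition!r}")
    types = event_types if event_types is not None else [f"loco_{condition}"]
    aligned = cf_events.collect_aligned(
        group, window_s=config.window_s, event_types=types,
        detector_kwargs=_detector_kwargs(config))
    aligned = cf_events.baseline_subtract(aligned, config.baseline_mode)
    return cf_events.triggered_average(
        aligned, n_boot=config.n_boot_timecourse, ci=config.ci, rng=rng)


def run_pipeline(config: PipelineConfig, in_dir: str | Path | None,
                 out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cf_io.config_hash(config)
    rng = np.random.default_rng(config.seed)
    report: dict[str, Any] = {"config_hash": chash, "seed": config.seed,
                              "stages": {}}
    geometry = default_geometry()

    # stage: synth (optional) or load
    if config.synth is not None:
        cohort = cf_synth.simulate_cohort(config.synth, rng=rng,
                                          geometry=geometry)
        sessions = cohort.sessions
        cf_io.write_cohort(cohort, out_dir / "sessions")
        report["stages"]["synth"] = {"n_sessions": len(sessions)}
    elif in_dir is not None:
        sessions = cf_io.read_sessions(in_dir)
        report["stages"]["load"] = {"n_sessions": len(sessions)}
    else:
        sessions = []
    if not sessions:
        report["stages"]["result"] = "no sessions"
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        return report

    # fail fast on impossible configs
    min_duration = min(s.duration_s for s in sessions)
    if config.detrend and config.detrend_window_s > min_duration:
        raise ValueError(
            f"detrend window {config.detrend_window_s} s exceeds the "
            f"shortest session ({min_duration} s)")

    # stage: preprocess
    try:
        sessions = [
            cf_pre.preprocess_session(
                s, do_detrend=config.detrend,
                window_s=config.detrend_window_s,
                percentile=config.detrend_percentile)
            for s in sessions
        ]
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"preprocess failed: {exc}") from exc
    report["stages"]["preprocess"] = {"n_sessions": len(sessions),
                                      "detrended": config.detrend}

    # stage: qc
    kept, excluded, qc_report = cf_pre.qc_exclude_sessions(
        sessions, level=config.qc_level,
        min_duration_s=config.qc_min_duration_s)
    for row in qc_report[qc_report["excluded"]].itertuples():
        logger.info("qc: excluded session %s (first offending window at "
                    "%.1f s)", row.session_id, row.first_offending_window_s)
    qc_report.drop(columns=["offending_windows"]).to_csv(
        out_dir / "qc_report.csv", index=False)
    report["stages"]["qc"] = {"kept": len(kept), "excluded": len(excluded)}
    sessions = kept
    if not sessions:
        report["stages"]["result"] = "all sessions excluded"
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        return report

    # stage: events
    event_tables = []
    n_onsets = n_invalid = 0
    for s in sessions:
        try:
            table = cf_events.detect_session_onsets(
                s, **_detector_kwargs(config))
        except Exception as exc:  # noqa: BLE001
            raise StageError(
                f"events failed on session {s.session_id}: {exc}") from exc
        table = table.assign(session_id=s.session_id, mouse_id=s.mouse_id)
        for row in table[~table["valid"]].itertuples():
            logger.info("events: onset at %.2f s in %s invalid: %s",
                        row.time_s, s.session_id, row.exclusion_reason)
        event_tables.append(table)
        n_onsets += int(table["valid"].sum())
        n_invalid += int((~table["valid"]).sum())
    events_frame = pd.concat(event_tables, ignore_index=True)
    events_frame.to_csv(out_dir / "events.csv", index=False)
    report["stages"]["events"] = {"valid_onsets": n_onsets,
                                  "invalid_onsets": n_invalid}

    # stage: averages + similarity (needs closed & open sessions)
    conditions = {s.condition for s in sessions}
    if {"closed", "open"} <= conditions:
        closed_avg = condition_average(sessions, "closed", config, rng)
        open_avg = condition_average(sessions, "open", config, rng)
        sim = cf_metrics.onset_similarity(
            closed_avg, open_avg, window_s=config.window_s,
            smooth_s=config.smooth_s)
        sim.per_roi.rename("r").to_csv(out_dir / "similarity_per_roi.csv")
        report["stages"]["similarity"] = {"mean": sim.mean, "sem": sim.sem}

    # stage: metrics (pair correlations + density)
    pairs = cf_metrics.pair_correlation_cohort(sessions, geometry)
    pairs.to_csv(out_dir / "pair_correlations.csv", index=False)
    density = cf_metrics.correlation_distance_density(
        pairs, n_bins=config.density_bins,
        sigma_bins=config.density_sigma_bins,
        d_range=config.d_range, r_range=config.r_range)
    np.savetxt(out_dir / "density_smoothed.csv", density.smoothed,
               delimiter=",")
    (out_dir / "density_meta.json").write_text(json.dumps({
        "d_edges": density.d_edges.tolist(),
        "r_edges": density.r_edges.tolist(),
        "sigma_bins": density.sigma_bins,
        "contour_level": density.contour_level,
        "peak_density": density.peak_density,
        "config_hash": chash,
    }, indent=1))
    report["stages"]["metrics"] = {"n_pairs": int(len(pairs))}

    # stage: drug change (needs naive + treated sessions)
    treatments = {s.treatment for s in sessions}
    treated = treatments - {"naive"}
    if "naive" in treatments and treated:
        before = cf_metrics.pair_correlation_cohort(
            [s for s in sessions if s.treatment == "naive"], geometry)
        after = cf_metrics.pair_correlation_cohort(
            [s for s in sessions if s.treatment != "naive"], geometry)
        change = cf_metrics.drug_change(before, after,
                                        cutoff=config.shortlong_cutoff)
        change.table.to_csv(out_dir / "drug_change.csv", index=False)
        change.summary.to_csv(out_dir / "drug_change_summary.csv",
                              index=False)
        long_vals = change.changes("long")
        short_vals = change.changes("short")
        w_stat, p = cf_stats.rank_sum(short_vals, long_vals) \
            if len(short_vals) and len(long_vals) else (np.nan, np.nan)
        report["stages"]["drug_change"] = {
            "n_short": int(len(short_vals)), "n_long": int(len(long_vals)),
            "median_short": float(np.median(short_vals))
            if len(short_vals) else None,
            "median_long": float(np.median(long_vals))
            if len(long_vals) else None,
            "ranksum_p_short_vs_long": None if np.isnan(p) else float(p),
        }

    # stage: stats (hierarchical bootstrap of speed-activity correlation)
    rows = []
    for s in sessions:
        r = cf_metrics.speed_activity_correlation(s)
        for roi, val in r.items():
            rows.append({"mouse": s.mouse_id, "session": s.session_id,
                         "condition": s.condition, "roi": roi, "r": val})
    speed_corr = pd.DataFrame(rows).dropna(subset=["r"])
    speed_corr.to_csv(out_dir / "speed_activity_correlation.csv",
                      index=False)
    if len(speed_corr) and speed_corr["mouse"].nunique() >= 1:
        sample = cf_stats.NestedSample(
            values=speed_corr["r"].to_numpy(),
            level1=speed_corr["mouse"].to_numpy(),
            level2=speed_corr["session"].to_numpy())
        est = cf_stats.hboot(sample, n_boot=config.n_boot, ci=config.ci,
                             rng=rng)
        (out_dir / "speed_corr_hboot.json").write_text(json.dumps(
            {**est.to_jsonable(), "config_hash": chash, "seed": config.seed},
            indent=1))
        report["stages"]["stats"] = {"speed_corr_mean": est.point,
                                     "ci": [est.ci_low, est.ci_high]}

    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
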