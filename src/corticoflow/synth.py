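"""Synthetic visuomotor cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
bout-structured locomotion on a spherical treadmill, closed-loop coupling
of visual flow to locomotion with 1-s mismatch halts, open-loop replay,
dark and drifting-grating sessions, and 12-ROI dF/F traces built from
behavioural drives plus shared latent factors, convolved with a
calcium-indicator kernel, with optional drift, noise and injectable
artifacts.  Every injected quantity is recorded in a
:class:`CohortGroundTruth` so downstream stages can be tested against it.

Latent structure
----------------
Three spatial scales of shared variance give distance-dependent
correlations:

- *local* factors anchored at the ROI centres, loadings decaying as
  ``exp(-d / loading_length_scale_mm)`` — nearby ROIs co-fluctuate;
- one factor per *area group* (anterior motor/cingulate, posterior
  visual/retrosplenial) loading equally on its 6 ROIs;
- one *long-range* factor loading equally on all 12 ROIs — the only
  source of anterior<->posterior coupling beyond behavioural drives.

The "drug" treatment multiplies the long-range shared variance by
``drug_longrange_scale`` (loadings scaled by its square root) and adds
ROI-private variance to make up the difference, i.e. the drug converts
shared long-range input into private input while preserving each ROI's
total variance.  The injected normalized long-range correlation change is
therefore ``scale - 1`` by construction.

Latent time courses are white noise filtered with the calcium kernel and
standardised to zero mean and unit sample variance, so the sample
covariance contributed by the loadings is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, ConfigError
from .geometry import RoiGeometry, default_geometry, is_posterior
from .session import Session

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ground truth bookkeeping


@dataclass
class ArtifactSpec:
    """One artifact to inject: kind in {'seizure', 'drift', 'hemodip'}.

    ``amplitude`` is the plateau height (seizure), total ramp height
    (drift), or dip depth (hemodip), in dF/F fraction.
    """

    kind: str
    start_s: float
    duration_s: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("seizure", "drift", "hemodip"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("artifact duration must be > 0")


@dataclass
class CohortGroundTruth:
    """Everything the generator injected, for recovery tests."""

    true_onsets: list[dict[str, Any]] = field(default_factory=list)
    latent_loadings: np.ndarray | None = None  # ROI x latent
    latent_names: list[str] = field(default_factory=list)
    roi_ids: list[str] = field(default_factory=list)
    treatment_scale_applied: dict[str, float] = field(default_factory=dict)
    artifact_windows: list[dict[str, Any]] = field(default_factory=list)

    def onsets_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_onsets)

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "true_onsets": self.true_onsets,
            "latent_loadings": None if self.latent_loadings is None
            else self.latent_loadings.tolist(),
            "latent_names": self.latent_names,
            "roi_ids": self.roi_ids,
            "treatment_scale_applied": self.treatment_scale_applied,
            "artifact_windows": self.artifact_windows,
        }


@dataclass
class Cohort:
    sessions: list[Session]
    truth: CohortGroundTruth
    cfg: SimConfig
    geometry: RoiGeometry

    def by_mouse(self) -> dict[str, list[Session]]:
        out: dict[str, list[Session]] = {}
        for s in self.sessions:
            out.setdefault(s.mouse_id, []).append(s)
        return out


# ---------------------------------------------------------------------------
# building blocks


def calcium_filter(x: np.ndarray, fs_hz: float, tau_s: float) -> np.ndarray:
    """Causal single-exponential indicator kernel, unit DC gain.

    y[t] = rho * y[t-1] + (1 - rho) * x[t] with rho = exp(-dt/tau): a step
    input settles to its own amplitude, so drive amplitudes stay in dF/F
    units after convolution.
    """
    from scipy.signal import lfilter

    rho = float(np.exp(-1.0 / (fs_hz * tau_s)))
    return lfilter([1.0 - rho], [1.0, -rho], np.asarray(x, dtype=float),
                   axis=-1)


def _standardised_latents(n_latents: int, n_samples: int, fs_hz: float,
                          tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """(n_latents, n_samples) kernel-filtered unit-variance time courses."""
    if n_latents == 0:
        return np.empty((0, n_samples))
    z = calcium_filter(rng.standard_normal((n_latents, n_samples)),
                       fs_hz, tau_s)
    z -= z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return z / sd


def latent_loadings(cfg: SimConfig, geometry: RoiGeometry) -> tuple[np.ndarray, list[str]]:
    """Deterministic ROI x latent loading matrix.

    Columns: ``n_latents`` local factors (anchored at the first
    ``n_latents`` ROI centres, cycled), then 'group_posterior',
    'group_anterior', then 'long_range'.
    """
    roi_ids = geometry.roi_ids
    n_roi = len(roi_ids)
    dmat = geometry.distance_matrix_mm(roi_ids)
    anchors = [i % n_roi for i in range(cfg.n_latents)]
    local = cfg.local_latent_dff * np.exp(
        -dmat[:, anchors] / cfg.loading_length_scale_mm)
    posterior = np.array([is_posterior(r) for r in roi_ids], dtype=float)
    group = np.column_stack([
        cfg.group_latent_dff * posterior,
        cfg.group_latent_dff * (1.0 - posterior),
    ])
    long_range = np.full((n_roi, 1), cfg.long_latent_dff)
    names = ([f"local_{roi_ids[a]}" for a in anchors]
             + ["group_posterior", "group_anterior", "long_range"])
    return np.hstack([local, group, long_range]), names


def model_covariance(cfg: SimConfig, geometry: RoiGeometry,
                     longrange_scale: float = 1.0,
                     include_noise: bool = True) -> np.ndarray:
    """Model ROI covariance implied by the latent loadings.

    Behavioural drives are excluded (they depend on the realised
    behaviour); under a long-range scale s the shared long-range
    contribution is s * w w' and the removed variance (1-s) w^2 returns on
    the diagonal as private variance.
    """
    load, names = latent_loadings(cfg, geometry)
    w = load[:, names.index("long_range")].copy()
    rest = np.delete(load, names.index("long_range"), axis=1)
    cov = rest @ rest.T
    cov += longrange_scale * np.outer(w, w)
    cov += np.diag((1.0 - longrange_scale) * w**2)
    if include_noise:
        cov += cfg.noise_sd**2 * np.eye(len(w))
    return cov


def model_correlation(cfg: SimConfig, geometry: RoiGeometry,
                      longrange_scale: float = 1.0,
                      include_noise: bool = True) -> np.ndarray:
    cov = model_covariance(cfg, geometry, longrange_scale, include_noise)
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# locomotion


def simulate_locomotion(
    duration_s: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    forced_bouts: Sequence[tuple[float, float, float]] | None = None,
    return_bouts: bool = False,
):
    """Two-state (quiescent/bout) locomotion speed trace at ``cfg.fs_hz``.

    Bouts rise to a plateau at ``max_accel_cms2`` (one sample at the
    defaults), hold it for an exponential duration, and decelerate at
    ``decel_cms2`` back to rest.  ``forced_bouts`` is a list of
    (start_s, plateau_cms, duration_s) overriding the random process.

    Returns the speed array, or (speed, bouts) where bouts is a DataFrame
    (start_s, plateau_cms, duration_s) when ``return_bouts`` is set.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s: must be > 0")
    fs = cfg.fs_hz
    dt = 1.0 / fs
    n = int(round(duration_s * fs))
    speed = np.zeros(n)

    if forced_bouts is not None:
        bouts = [{"start_s": float(t), "plateau_cms": float(p),
                  "duration_s": float(d)} for t, p, d in forced_bouts]
    else:
        bouts = []
        if cfg.bout_rate_hz > 0:
            t = cfg.min_quiescent_s + rng.exponential(1.0 / cfg.bout_rate_hz)
            while t < duration_s:
                plateau = float(np.clip(
                    rng.normal(cfg.bout_speed_cms, cfg.bout_speed_sd_cms),
                    5.0, 3.0 * cfg.bout_speed_cms))
                dur = float(np.clip(rng.exponential(cfg.bout_duration_s),
                                    1.0, 15.0))
                bouts.append({"start_s": t, "plateau_cms": plateau,
                              "duration_s": dur})
                rise = plateau / cfg.max_accel_cms2
                fall = plateau / cfg.decel_cms2
                t += rise + dur + fall
                t += cfg.min_quiescent_s + rng.exponential(1.0 / cfg.bout_rate_hz)

    rise_step = cfg.max_accel_cms2 * dt
    fall_step = cfg.decel_cms2 * dt
    for bout in bouts:
        i = int(round(bout["start_s"] * fs))
        plateau = bout["plateau_cms"]
        n_rise = int(np.ceil(plateau / rise_step))
        for k in range(n_rise):
            if i >= n:
                break
            speed[i] = max(speed[i], min(plateau, (k + 1) * rise_step))
            i += 1
        i_end = min(n, int(round((bout["start_s"] + bout["duration_s"]) * fs))
                    + n_rise)
        speed[i:i_end] = plateau
        i = i_end
        level = plateau
        while level > 0 and i < n:
            level -= fall_step
            if level <= 0:
                break
            speed[i] = max(speed[i], level)
            i += 1

    if return_bouts:
        cols = ["start_s", "plateau_cms", "duration_s"]
        frame = pd.DataFrame(bouts, columns=cols)
        return speed, frame
    return speed


# ---------------------------------------------------------------------------
# sessions


def _poisson_times(rate_hz: float, duration_s: float, margin_s: float,
                   min_gap_s: float, rng: np.random.Generator) -> np.ndarray:
    """Random event times in [margin, duration - margin] with a minimum gap."""
    if rate_hz <= 0 or duration_s <= 2 * margin_s:
        return np.array([])
    count = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(margin_s, duration_s - margin_s, size=count))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap_s:
            kept.append(float(t))
    return np.array(kept)


def _grating_schedule(duration_s: float, cfg: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    t = max(1.0, rng.normal(cfg.grating_interval_mean_s,
                            cfg.grating_interval_sd_s))
    while t < duration_s - 1.0:
        dur = max(1.0, rng.normal(cfg.grating_duration_mean_s,
                                  cfg.grating_duration_sd_s))
        rows.append({"time_s": float(t), "type": "grating",
                     "duration_s": float(min(dur, duration_s - t))})
        t += dur + max(0.5, rng.normal(cfg.grating_interval_mean_s,
                                       cfg.grating_interval_sd_s))
    return pd.DataFrame(rows, columns=["time_s", "type", "duration_s"])


def simulate_session(
    condition: str,
    treatment: str,
    cfg: SimConfig,
    truth: CohortGroundTruth | None,
    rng: np.random.Generator,
    mouse_id: str = "m0",
    session_id: str = "s0",
    geometry: RoiGeometry | None = None,
    replay_flow: np.ndarray | None = None,
    forced_bouts: Sequence[tuple[float, float, float]] | None = None,
) -> Session:
    """Simulate one recording under the given condition and treatment.

    Closed loop couples visual flow to locomotion (``coupling_gain``) with
    1-s mismatch halts; open loop replays either ``replay_flow`` or an
    independent locomotion draw; dark has no flow; grating presents
    drifting gratings with 6 +/- 2 s durations and 4.5 +/- 1.5 s
    intervals.  All injected quantities are appended to ``truth``.
    """
    if condition not in ("closed", "open", "dark", "grating"):
        raise ValueError(f"unknown condition {condition!r}")
    if treatment not in ("naive", "drug", "saline"):
        raise ValueError(f"unknown treatment {treatment!r}")
    geometry = geometry if geometry is not None else default_geometry()
    roi_ids = geometry.roi_ids
    n_roi = len(roi_ids)
    fs = cfg.fs_hz
    n = cfg.n_samples
    duration = cfg.session_duration_s

    speed, bouts = simulate_locomotion(duration, cfg, rng,
                                       forced_bouts=forced_bouts,
                                       return_bouts=True)

    markers = pd.DataFrame(columns=["time_s", "type", "duration_s"])
    mismatch_box = np.zeros(n)
    grating_box = np.zeros(n)

    if condition == "closed":
        flow = cfg.coupling_gain * speed
        mm_times = _poisson_times(cfg.mismatch_rate_hz, duration,
                                  margin_s=5.0,
                                  min_gap_s=2.0 * cfg.mismatch_duration_s,
                                  rng=rng)
        for t in mm_times:
            i0 = int(round(t * fs))
            i1 = min(n, i0 + int(round(cfg.mismatch_duration_s * fs)))
            flow[i0:i1] = 0.0
            mismatch_box[i0:i1] = 1.0
        markers = pd.DataFrame({
            "time_s": mm_times, "type": "mismatch",
            "duration_s": cfg.mismatch_duration_s,
        }, columns=["time_s", "type", "duration_s"])
    elif condition == "open":
        if replay_flow is not None:
            if replay_flow.shape != (n,):
                raise ValueError("replay_flow length does not match session")
            flow = replay_flow.astype(float).copy()
        else:
            flow = cfg.coupling_gain * simulate_locomotion(duration, cfg, rng)
    elif condition == "grating":
        flow = np.zeros(n)
        markers = _grating_schedule(duration, cfg, rng)
        for row in markers.itertuples():
            i0 = int(round(row.time_s * fs))
            i1 = min(n, i0 + int(round(row.duration_s * fs)))
            grating_box[i0:i1] = 1.0
    else:  # dark
        flow = np.zeros(n)

    # behavioural drives, in dF/F units, through the indicator kernel
    ref = cfg.bout_speed_cms
    posterior = np.array([is_posterior(r) for r in roi_ids], dtype=float)
    a = np.full(n_roi, cfg.loco_drive_dff)
    b = np.where(posterior > 0, cfg.visual_drive_posterior_dff,
                 cfg.visual_drive_anterior_dff)
    m = cfg.mismatch_amp_dff * posterior
    visual_input = flow / ref + grating_box
    drives = (a[:, None] * (speed / ref)[None, :]
              + b[:, None] * visual_input[None, :]
              + m[:, None] * mismatch_box[None, :])
    traces = calcium_filter(drives, fs, cfg.calcium_tau_s)

    # shared latent factors
    load, names = latent_loadings(cfg, geometry)
    scale = cfg.drug_longrange_scale if treatment == "drug" else 1.0
    load_eff = load.copy()
    i_long = names.index("long_range")
    load_eff[:, i_long] *= np.sqrt(scale)
    latents = _standardised_latents(load.shape[1], n, fs,
                                    cfg.calcium_tau_s, rng)
    traces += load_eff @ latents
    if scale < 1.0:
        # private make-up variance: keeps per-ROI variance constant
        private_sd = load[:, i_long] * np.sqrt(1.0 - scale)
        private = _standardised_latents(n_roi, n, fs, cfg.calcium_tau_s, rng)
        traces += private_sd[:, None] * private

    if cfg.drift_slope != 0.0:
        t_min = np.arange(n) / fs / 60.0
        traces += cfg.drift_slope * t_min[None, :]
    if cfg.noise_sd > 0:
        traces += rng.normal(0.0, cfg.noise_sd, size=(n_roi, n))

    session = Session(
        traces=traces, roi_ids=list(roi_ids), speed=speed, flow=flow,
        fs_hz=fs, mouse_id=mouse_id, session_id=session_id,
        condition=condition, treatment=treatment, traces_kind="dff",
        markers=markers,
        meta={"longrange_scale": scale},
    )

    if truth is not None:
        for bout in bouts.itertuples():
            truth.true_onsets.append({
                "mouse": mouse_id, "session": session_id,
                "time_s": float(bout.start_s), "type": "bout",
                "plateau_cms": float(bout.plateau_cms),
                "duration_s": float(bout.duration_s),
            })
        for row in markers.itertuples():
            truth.true_onsets.append({
                "mouse": mouse_id, "session": session_id,
                "time_s": float(row.time_s), "type": str(row.type),
            })
        truth.treatment_scale_applied[session_id] = scale
        if truth.latent_loadings is None:
            truth.latent_loadings = load
            truth.latent_names = names
            truth.roi_ids = list(roi_ids)
    return session


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    cfg: SimConfig,
    conditions: Sequence[str] = ("closed", "open"),
    treatment: str = "naive",
    geometry: RoiGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """``n_mice`` mice x ``sessions_per_condition`` sessions per condition.

    With ``cfg.replay_from_session`` the open-loop flow replays the same
    mouse's closed-loop flow traces (the paired experimental design);
    otherwise open-loop flow comes from an independent locomotion draw.
    """
    geometry = geometry if geometry is not None else default_geometry()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = CohortGroundTruth()
    sessions: list[Session] = []
    for im in range(cfg.n_mice):
        mouse = f"m{im:02d}"
        closed_flows: list[np.ndarray] = []
        for cond in conditions:
            for k in range(cfg.sessions_per_condition):
                sid = f"{mouse}_{cond}_{treatment}_{k:02d}"
                replay = None
                if (cond == "open" and cfg.replay_from_session
                        and closed_flows):
                    replay = closed_flows[k % len(closed_flows)]
                sess = simulate_session(cond, treatment, cfg, truth, rng,
                                        mouse_id=mouse, session_id=sid,
                                        geometry=geometry, replay_flow=replay)
                if cond == "closed":
                    closed_flows.append(sess.flow)
                sessions.append(sess)
    return Cohort(sessions=sessions, truth=truth, cfg=cfg, geometry=geometry)


def simulate_treatment_cohort(
    cfg: SimConfig,
    condition: str = "dark",
    treatment: str = "drug",
    geometry: RoiGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Before/after design: per mouse, ``sessions_per_condition`` naive
    sessions followed by the same number under ``treatment``."""
    geometry = geometry if geometry is not None else default_geometry()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = CohortGroundTruth()
    sessions: list[Session] = []
    for im in range(cfg.n_mice):
        mouse = f"m{im:02d}"
        for phase in ("naive", treatment):
            for k in range(cfg.sessions_per_condition):
                sid = f"{mouse}_{condition}_{phase}_{k:02d}"
                sessions.append(simulate_session(
                    condition, phase, cfg, truth, rng, mouse_id=mouse,
                    session_id=sid, geometry=geometry))
    return Cohort(sessions=sessions, truth=truth, cfg=cfg, geometry=geometry)


# ---------------------------------------------------------------------------
# artifacts


def _merge_seizure_windows(specs: list[ArtifactSpec]) -> list[ArtifactSpec]:
    seizures = sorted((s for s in specs if s.kind == "seizure"),
                      key=lambda s: s.start_s)
    merged: list[ArtifactSpec] = []
    for s in seizures:
        if merged and s.start_s <= merged[-1].start_s + merged[-1].duration_s:
            prev = merged[-1]
            end = max(prev.start_s + prev.duration_s,
                      s.start_s + s.duration_s)
            logger.warning(
                "overlapping seizure windows merged: [%.2f, %.2f] + "
                "[%.2f, %.2f]", prev.start_s,
                prev.start_s + prev.duration_s, s.start_s,
                s.start_s + s.duration_s)
            merged[-1] = ArtifactSpec("seizure", prev.start_s,
                                      end - prev.start_s,
                                      max(prev.amplitude, s.amplitude))
        else:
            merged.append(s)
    return merged + [s for s in specs if s.kind != "seizure"]


def inject_artifacts(session: Session, specs: Sequence[ArtifactSpec],
                     truth: CohortGroundTruth | None = None) -> Session:
    """Return a copy of the session with artifacts added to all ROI traces.

    seizure: plateau of ``amplitude`` added over the window (all ROIs);
    drift: linear ramp from 0 to ``amplitude`` across the window;
    hemodip: transient negative Gaussian deflection of depth ``amplitude``.
    Overlapping seizure windows are merged with a warning in the log.
    """
    out = session.copy()
    fs = session.fs_hz
    n = session.n_samples
    for spec in specs:
        if spec.start_s < 0 or spec.start_s + spec.duration_s > session.duration_s:
            raise ValueError(
                f"artifact window [{spec.start_s}, "
                f"{spec.start_s + spec.duration_s}] s outside session "
                f"bounds [0, {session.duration_s}] s")
    for spec in _merge_seizure_windows(list(specs)):
        i0 = int(round(spec.start_s * fs))
        i1 = min(n, i0 + int(round(spec.duration_s * fs)))
        width = i1 - i0
        if width <= 0:
            continue
        if spec.kind == "seizure":
            out.traces[:, i0:i1] += spec.amplitude
        elif spec.kind == "drift":
            out.traces[:, i0:i1] += spec.amplitude * np.linspace(0, 1, width)
        else:  # hemodip
            t = np.arange(width) / fs
            center = spec.duration_s / 2.0
            sigma = max(spec.duration_s / 4.0, 1.0 / fs)
            out.traces[:, i0:i1] -= spec.amplitude * np.exp(
                -0.5 * ((t - center) / sigma) ** 2)
        if truth is not None:
            truth.artifact_windows.append({
                "session": session.session_id, "start_s": spec.start_s,
                "end_s": spec.start_s + spec.duration_s, "kind": spec.kind,
            })
    return out
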