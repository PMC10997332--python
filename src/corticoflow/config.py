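"""Configuration objects for the synthetic generator and the pipeline.

All thresholds that the analysis quotes in percent dF/F ("30%", "1%") are
stored here as dimensionless fractions; the conversion happens once at
this boundary and nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {message}")


@dataclass
class SimConfig:
    """Parameters of the synthetic visuomotor cohort generator.

    Amplitudes with the ``_dff`` suffix are in dF/F fraction units (0.05 is
    a 5% dF/F signal); speeds are cm/s, lengths mm, times seconds.

    The ROI signal model is a sum of behavioural drives (locomotion, visual
    flow, mismatch) convolved with a calcium-indicator kernel, plus shared
    latent factors at three spatial scales: local factors anchored at the
    ROI centres with exponentially decaying loadings, one factor per
    anterior/posterior area group, and a single global long-range factor
    coupling the anterior and posterior groups.  The "drug" treatment
    multiplies the long-range shared variance by ``drug_longrange_scale``
    and replaces the removed shared variance with ROI-private variance, so
    total per-ROI variance is preserved while long-range correlations scale
    by the configured factor.
    """

    # cohort layout
    n_mice: int = 5
    sessions_per_condition: int = 4
    fs_hz: float = 100.0
    session_duration_s: float = 300.0

    # locomotion bout process (two-state semi-Markov)
    bout_rate_hz: float = 0.033
    bout_duration_s: float = 4.0
    bout_speed_cms: float = 40.0
    bout_speed_sd_cms: float = 8.0
    max_accel_cms2: float = 5000.0
    decel_cms2: float = 100.0
    min_quiescent_s: float = 4.0

    # visuomotor coupling and stimuli
    coupling_gain: float = 1.0
    mismatch_rate_hz: float = 0.02
    mismatch_duration_s: float = 1.0
    grating_duration_mean_s: float = 6.0
    grating_duration_sd_s: float = 2.0
    grating_interval_mean_s: float = 4.5
    grating_interval_sd_s: float = 1.5
    replay_from_session: bool = False

    # latent factor structure
    n_latents: int = 12
    loading_length_scale_mm: float = 0.8
    local_latent_dff: float = 0.06
    group_latent_dff: float = 0.07
    long_latent_dff: float = 0.06
    drug_longrange_scale: float = 1.0

    # behavioural drives onto ROIs
    loco_drive_dff: float = 0.04
    visual_drive_posterior_dff: float = -0.06
    visual_drive_anterior_dff: float = 0.01
    mismatch_amp_dff: float = 0.06

    # indicator, noise, drift
    calcium_tau_s: float = 0.5
    noise_sd: float = 0.05
    drift_slope: float = 0.01  # dF/F fraction per minute

    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_mice >= 1, "n_mice", "must be >= 1")
        _require(self.sessions_per_condition >= 1, "sessions_per_condition", "must be >= 1")
        _require(self.fs_hz > 0, "fs_hz", "must be > 0")
        _require(self.session_duration_s > 0, "session_duration_s", "must be > 0")
        n = self.fs_hz * self.session_duration_s
        _require(abs(n - round(n)) < 1e-9, "session_duration_s",
                 "fs_hz * session_duration_s must be an integer sample count")
        _require(self.bout_rate_hz >= 0, "bout_rate_hz", "must be >= 0")
        for name in ("bout_duration_s", "bout_speed_cms", "max_accel_cms2",
                     "decel_cms2", "min_quiescent_s", "mismatch_duration_s",
                     "grating_duration_mean_s", "grating_interval_mean_s",
                     "calcium_tau_s", "loading_length_scale_mm"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.mismatch_rate_hz >= 0, "mismatch_rate_hz", "must be >= 0")
        _require(0.0 <= self.drug_longrange_scale <= 1.0,
                 "drug_longrange_scale", "must lie in [0, 1]")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.n_latents >= 0, "n_latents", "must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.session_duration_s))

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


#: Baseline-subtraction windows, seconds relative to onset.
BASELINE_WINDOWS: dict[str, tuple[float, float]] = {
    "stimulus": (-0.2, 0.0),      # unpredictable stimuli (mismatch, grating)
    "onset_gcamp": (-2.9, -2.7),  # locomotion / flow onsets, GCaMP
    "onset_egfp": (-0.9, -0.7),   # locomotion / flow onsets, eGFP controls
}


@dataclass
class PipelineConfig:
    """Every analysis default, with units, in one validated record."""

    # preprocessing
    detrend: bool = True
    detrend_window_s: float = 62.5
    detrend_percentile: float = 0.08
    qc_level: float = 0.30            # dF/F fraction
    qc_min_duration_s: float = 10.0

    # onset detection
    onset_threshold_cms: float = 30.0
    exclusion_window_s: float = 3.0   # 1.0 for eGFP sessions
    quiescence_cms: float = 1.0

    # event-triggered averaging
    window_s: tuple[float, float] = (-5.0, 3.0)
    baseline_mode: str = "onset_gcamp"
    n_boot_timecourse: int = 1000

    # similarity
    smooth_s: float = 1.0
    min_resp: float = 0.01            # dF/F fraction

    # correlation / density / drug change
    density_bins: int = 40
    density_sigma_bins: float = 1.0
    d_range: tuple[float, float] = (0.0, 1.6)
    r_range: tuple[float, float] = (-0.25, 1.0)
    shortlong_cutoff: float = 0.9

    # inference
    n_boot: int = 10000
    ci: float = 0.90

    seed: int = 0
    synth: SimConfig | None = None

    def __post_init__(self) -> None:
        _require(self.detrend_window_s > 0, "detrend_window_s", "must be > 0")
        _require(0 < self.detrend_percentile < 1, "detrend_percentile",
                 "must be a fraction in (0, 1)")
        _require(self.qc_level > 0, "qc_level", "must be > 0")
        _require(self.qc_min_duration_s > 0, "qc_min_duration_s", "must be > 0")
        _require(self.onset_threshold_cms > 0, "onset_threshold_cms", "must be > 0")
        _require(self.exclusion_window_s >= 0, "exclusion_window_s", "must be >= 0")
        _require(self.quiescence_cms >= 0, "quiescence_cms", "must be >= 0")
        _require(self.window_s[0] < self.window_s[1], "window_s",
                 "pre must be earlier than post")
        _require(self.baseline_mode in BASELINE_WINDOWS, "baseline_mode",
                 f"must be one of {sorted(BASELINE_WINDOWS)}")
        _require(self.n_boot >= 1, "n_boot", "must be >= 1")
        _require(self.n_boot_timecourse >= 1, "n_boot_timecourse", "must be >= 1")
        _require(0 < self.ci < 1, "ci", "must be a fraction in (0, 1)")
        _require(self.density_bins >= 1, "density_bins", "must be >= 1")
        _require(self.density_sigma_bins >= 0, "density_sigma_bins", "must be >= 0")
        _require(self.shortlong_cutoff > 0, "shortlong_cutoff", "must be > 0")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        """Build from a plain mapping (e.g. parsed YAML); unknown keys are
        rejected rather than silently ignored."""
        raw = dict(raw)
        synth_raw = raw.pop("synth", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_s", "d_range", "r_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        synth = None
        if synth_raw is not None:
            known_s = {f.name for f in dataclasses.fields(SimConfig)}
            unknown_s = set(synth_raw) - known_s
            if unknown_s:
                raise ConfigError(f"unknown synth config keys: {sorted(unknown_s)}")
            synth = SimConfig(**synth_raw)
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("window_s", "d_range", "r_range"):
            d[key] = list(d[key])
        return d
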