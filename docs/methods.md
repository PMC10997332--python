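# Methods

`corticoflow` analyses widefield calcium-imaging recordings of mouse
dorsal cortex acquired in a visuomotor virtual-reality paradigm: 5-minute
sessions in which a head-fixed mouse runs on a spherical treadmill while
visual flow in a virtual corridor is either coupled to locomotion
(closed loop), replayed from earlier recordings (open loop), absent
(dark), or replaced by drifting gratings.  Activity is summarised as
ΔF/F in 12 regions of interest (V1, V2am, RSC, M1, A24b, M2 in each
hemisphere).  This note documents the processing and statistical
procedures, the synthetic-cohort generator used for validation, and the
numerical conventions the implementation commits to.

## Preprocessing

**ΔF/F.** For each ROI, ΔF/F = (F − F₀)/F₀ with F₀ the *median*
fluorescence of the whole recording.  The output median is therefore
exactly zero and the transform is invariant to detector gain.  A
non-positive median (dead trace) is an error, not a silent NaN.

**Drift correction.** Slow drift — e.g. thermal brightening of the
excitation LED — is removed by subtracting a running 8th-percentile
baseline computed in a 62.5 s moving window (15 s is the conventional
window for two-photon data; both are `PipelineConfig` fields).  The
window is *centred* with truncation at the session edges; a trailing
window would phase-lag the baseline and leak drift into onset-locked
averages.  The percentile is numpy's linear-interpolation quantile, so a
naive per-sample reimplementation reproduces the output bit-exactly —
the test suite holds the fast implementation to that standard.
ΔF/F is computed first, detrending second.

**Quality control.** Sessions showing seizure-like events — the mean
ΔF/F across all 12 ROIs staying above 0.30 (30%) continuously for
*strictly more than* 10 s — are excluded.  An elevation lasting exactly
10.0 s is kept.  All thresholds quoted in percent are stored as
fractions; the conversion happens once, in `PipelineConfig`.

## Event detection and triggered averages

A locomotion (or visual-flow) onset is the first sample at or above a
30 cm/s threshold.  To keep only well-isolated onsets, a candidate is
valid iff neither the locomotion nor the visual-flow trace exceeds a
quiescence level (default 1 cm/s) at *any* sample of the 3 s exclusion
window preceding the crossing (1 s for eGFP-control data, which has
fewer usable onsets).  For visual-flow onsets the traces swap roles, so
the same symmetric rule enforces that the mouse was not locomoting
before flow onset.  Candidates whose exclusion window precedes the
recording start are invalid ("pre-window out of bounds"); onset time is
not interpolated below the 10 ms bin.

Snippets of all ROI traces are cut in a (−5 s, +3 s) window at the
native 10 ms bin; events whose window would cross the session bounds are
dropped, never zero-padded.  Baseline subtraction removes the per-onset,
per-ROI mean over a mode-specific window: (−200, 0) ms for unpredictable
stimuli (mismatch and grating onsets), (−2900, −2700) ms for
locomotion/flow onsets in GCaMP data (clearing indicator offset dynamics
and anticipatory activity), (−900, −700) ms for eGFP data.  The
subtraction is exact and idempotent.

Triggered averages pool onsets; uncertainty is a per-bin 90%
hierarchical-bootstrap band (below).  `linear_sum` combines two
responses the way per-animal summaries are reported: average within each
mouse, sum the per-mouse means, and report mean ± SEM over mice.

## Similarity of closed- and open-loop responses

Per ROI, similarity is the Pearson correlation between the averaged
closed-loop and open-loop onset responses after a centred 1 s moving
average, restricted to the (−5, +3) s window; the summary is mean ± SEM
over the 12 ROIs.  The per-mouse V1 variant averages onsets per
hemisphere, correlates the two condition averages per hemisphere, and
averages the left and right coefficients; mice whose peak |response| is
below 1% ΔF/F in either condition are excluded (correlation of
noise-level traces is meaningless).

## Pairwise correlations, distance, and drug-induced change

For every session, Pearson correlations are computed for all 66 pairs of
the 12 ROIs; each pair's Euclidean distance in the top-view plane (an
approximation of axonal path length) is normalised by the animal's
bregma-lambda distance (default 4.2 mm).  Pair density over
(distance, r) is binned on a fixed 40×40 grid (d ∈ [0, 1.6],
r ∈ [−0.25, 1] by default, so maps are comparable across cohorts) and
smoothed with a Gaussian filter (σ = 1 bin).  Points outside the ranges
are clipped into the outer bins and the smoothed field is renormalised
to the raw-grid mass, so total mass always equals the pair count; the
contour is drawn at 50% of the smoothed peak.

The drug effect per (mouse, pair) is (r_after − r_before)/r_before,
with session coefficients averaged within each side first.  Pairs are
split at 0.9 bregma-lambda units (≈ 3.8 mm); the boundary itself counts
as long-range.  Pairs with r_before exactly zero are dropped with a
logged count.  Pooled changes are summarised as median, quartiles, mean
and 1.5×IQR whiskers.  Fig-5-style condition pooling averages
per-session coefficients rather than concatenating sessions
(concatenation is available by flag); per-session averaging matches how
every other per-mouse summary in the pipeline is built.

## Hierarchical bootstrap and tests

Nested data (values within sessions or onsets, within mice) are
resampled in two stages: mice with replacement, then the level-2 units
of each selected mouse with replacement, the second-stage resample size
equalling that mouse's unit count.  The mean of each resample, repeated
10,000 times (1,000 for per-bin time-course bands), forms the bootstrap
distribution; the CI is the central 90% quantile interval and one-sided
p-values are the proportion of bootstrap means beyond zero, with exact
ties split evenly between tails.  For time courses one (mice, onsets)
resample is shared across all bins of a replicate so the band is
trace-coherent; independent per-bin resampling is available by flag.
Replicate means are computed as resampling-count-weighted means, which
vectorises the whole computation.  Family-wise error is controlled by
the adjusted threshold α/m.  A single-mouse input degrades to a plain
onset-level bootstrap with a logged warning.

The rank-sum test uses midranks; for groups of ≤ 10 values each the
two-sided p is permutation-exact (a subset-sum count over doubled
midranks, so ties are exact too; p = 2·min(tails), capped at 1), larger
groups use the tie-corrected normal approximation without continuity
correction.  One-way ANOVA uses the classical F with documented
degenerate conventions (no variance anywhere → F = 0, p = 1; zero
within-group variance with separated means → F = +∞, p = 0), followed by
per-group plain-bootstrap p-values.

## Synthetic cohorts

The generator produces mice × sessions with known ground truth for every
downstream stage.  Defaults: 5 mice, 4 sessions per condition, 300 s at
100 Hz.

**Locomotion** is a two-state semi-Markov process: quiescent gaps
(4 s minimum plus an exponential holding time, rate 0.033 Hz) alternate
with bouts whose plateau speed is Normal(40, 8) cm/s and whose duration
is exponential (mean 4 s, clipped to 1–15 s).  Bout initiation
accelerates to plateau within one 10 ms sample at the default
5000 cm/s² limit; deceleration is slow (100 cm/s²).  The near-step rise
is deliberate: the onset-validity rule demands full quiescence up to the
threshold crossing, so any slower ramp would disqualify every onset.
Real mice accelerate over one to two hundred milliseconds; the generator
trades that realism for a clean supply of valid onsets.  No published
bout statistics constrain these defaults; they were chosen once to give
roughly 5 supra-threshold, well-separated bouts per 5-minute session.

**Conditions.** Closed loop sets flow = gain × speed except during 1 s
mismatch halts injected at random times (0.02 Hz); open loop replays
either an independent locomotion draw (default) or the same mouse's
stored closed-loop flow (`replay_from_session`, the paired experimental
design); dark has no flow; grating presents onsets of 6 ± 2 s duration
with 4.5 ± 1.5 s intervals.

**ROI signals.** Each ROI trace is a sum of behavioural drives
(locomotion 0.04 ΔF/F at reference speed; visual flow −0.06 for
posterior, +0.01 for anterior areas; mismatch +0.06 in posterior areas)
convolved with a single-exponential calcium kernel (τ = 0.5 s,
unit DC gain, so drive amplitudes stay in ΔF/F units), plus shared
latent factors, linear drift (0.01 ΔF/F per minute) and white
measurement noise (SD 0.05).  The opposing posterior visual drive makes
posterior net responses negative during closed-loop locomotion but
positive in open loop — the qualitative deep-layer signature the
similarity analysis is designed to detect.

**Latent structure.**  Three spatial scales of shared variance give
distance-dependent correlations: local factors anchored at the 12 ROI
centres with loadings 0.06·exp(−d/0.8 mm); one factor per area group
(anterior motor/cingulate, posterior visual/retrosplenial; loading
0.07); and one global long-range factor (loading 0.06 on all 12 ROIs),
the only source of anterior↔posterior coupling beyond the behavioural
drives.  Group factors are needed because, with any smooth distance
decay alone, pairs at 2–3.5 mm (still short-range under the 0.9 cutoff)
would have essentially no short-scale coupling and would behave like
long-range pairs under the drug transform.  With the default geometry
every between-group pair is long-range, so the unscaled group factors do
not bias long-range recovery.  Latent time courses are white noise
filtered by the calcium kernel and standardised to unit sample variance,
making the loading-implied covariance exact per session;
`synth.model_correlation` returns the implied ROI correlation matrix for
ground-truth comparisons.

**Drug transform.** Under "drug" treatment the long-range *shared
variance* is multiplied by `drug_longrange_scale` s (loadings scaled by
√s) and the removed variance returns as ROI-private signal, preserving
each ROI's total variance — the drug decorrelates without silencing.
Long-range correlations therefore scale by s and the normalised change
(r_after − r_before)/r_before injected by the generator equals s − 1 by
construction, which is what the recovery analysis must estimate.
"Saline" applies scale 1.

**Artifacts.** Injectable seizure plateaus (additive, all ROIs), drift
ramps and hemodynamic-style dips, all recorded in the ground truth, let
the QC rule be tested against known windows.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` run everything from
scratch on one CPU.  Sizes were fixed as follows: oracle equivalence of
the running percentile on 50 traces of 100–5,000 samples; onset-detector
oracle equivalence on 100 bout traces; bootstrap calibration on 1,000
null cohorts of 10 mice × 5 sessions with mouse-level random-effect SD
equal to the within-mouse SD (n_boot = 1,000); decorrelation recovery on
cohorts of 5 mice with 8 dark sessions per phase — a scaled-down
stand-in for the study design, which pools several dozen pre- and
post-injection sessions per mouse; drug/saline discrimination on 100
repetitions of further size-reduced cohorts (4 mice, 2 sessions per
phase, 150 s at 50 Hz); similarity on the default 5 mice × 4 sessions
per condition.  Recovery and similarity cohorts are generated without
drift and analysed without the percentile detrend: exact detrending of
hundreds of full-length traces is the one expensive primitive, and its
correctness is already pinned sample-for-sample by the oracle test.

## Limitations

Passing these tests shows the pipeline implements its rules exactly and
recovers parameters from data that satisfy the generator's assumptions.
The generator does not emulate pixel-level data (beyond small movies for
the response-map helper), hemodynamic occlusion beyond a stylised dip,
indicator nonlinearities, day-to-day non-stationarity, or realistic bout
kinematics; conclusions about real recordings rest on the rule-level
fidelity, not on these simulations.  ROI coordinates are user-supplied —
there is no atlas registration — and per-mouse geometry differences
(which change each animal's short/long pair split) are supported but not
simulated by default.
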