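# corticoflow

Analysis pipeline for widefield calcium imaging of mouse dorsal cortex
in visuomotor virtual-reality experiments — ΔF/F preprocessing,
locomotion/visual-flow onset detection, event-triggered averaging with
hierarchical-bootstrap uncertainty, and distance-resolved inter-areal
correlation analysis — together with a synthetic-cohort generator that
makes every stage testable against known ground truth.

It is written for systems neuroscientists who record ROI-level
fluorescence (12 areas: V1, V2am, RSC, M1, A24b, M2 per hemisphere)
alongside treadmill locomotion and visual-flow speed, in closed-loop,
open-loop (replay), dark and grating sessions, and who want the full
path from raw traces to population statistics as tested, reusable code.

## What it computes

- **ΔF/F and drift correction**: ΔF/F = (F − F₀)/F₀ with F₀ the median
  of the recording; slow drift removed by subtracting a running
  8th-percentile baseline (62.5 s centred window). Sessions whose
  across-ROI mean ΔF/F stays above 30% for more than 10 s are excluded.
- **Onsets and triggered averages**: onsets are upward crossings of a
  30 cm/s speed threshold preceded by 3 s of quiescence on both
  behaviour traces; responses are aligned in a (−5, +3) s window at
  10 ms bins, baseline-subtracted, and averaged with a per-bin 90%
  hierarchical-bootstrap band (resampling mice, then onsets).
- **Closed/open-loop similarity**: per ROI, the Pearson correlation of
  the two averaged onset responses (1 s moving average, −5 to +3 s),
  summarised over ROIs or per mouse in V1.
- **Correlation vs distance**: Pearson r for all 66 ROI pairs per 5-min
  session, pair distance normalised by the bregma–lambda distance;
  40×40 density maps with Gaussian smoothing and half-peak contours;
  treatment effects as the normalised change
  (r_after − r_before)/r_before, split into short- and long-range pairs
  at 0.9 bregma–lambda units.
- **Inference**: two-stage hierarchical bootstrap of the mean (10,000
  resamples, 90% CI, tail-proportion p-values), family-wise correction
  α/m, exact-enumeration Wilcoxon rank-sum for small groups, one-way
  ANOVA with bootstrap follow-up.
- **Synthetic cohorts** (`corticoflow.synth`): bout-structured
  locomotion, closed-loop coupling with 1-s mismatch halts, open-loop
  replay, latent factors giving distance-dependent correlations, a
  calcium kernel, drift, noise, injectable artifacts, and a "drug"
  transform that scales long-range shared variance by a known factor —
  all recorded in a ground-truth sidecar.

## Worked example

Simulate a before/after cohort in which the treatment halves the
long-range coupling, then recover that effect from the traces:

```python
import numpy as np
from corticoflow.config import SimConfig
from corticoflow.geometry import default_geometry
from corticoflow import synth, metrics

cfg = SimConfig(drug_longrange_scale=0.5, drift_slope=0.0, seed=0)
geometry = default_geometry()
cohort = synth.simulate_treatment_cohort(cfg, condition="dark",
                                         treatment="drug", geometry=geometry)
before = metrics.pair_correlation_cohort(
    [s for s in cohort.sessions if s.treatment == "naive"], geometry)
after = metrics.pair_correlation_cohort(
    [s for s in cohort.sessions if s.treatment == "drug"], geometry)
res = metrics.drug_change(before, after, cutoff=0.9)
print(res.summary[["range", "n", "median", "q1", "q3"]].round(3).to_string(index=False))
```

prints

```
range   n  median     q1     q3
short 135  -0.181 -0.197 -0.163
 long 195  -0.440 -0.490 -0.364
```

i.e. across 195 long-range pair changes (5 mice × 39 pairs) the median
normalised correlation change is −0.44 — recovering the injected factor
0.5 (expected change 0.5 − 1 = −0.5) — while the 135 short-range pairs
change far less, the signature of a selective long-range decorrelation.

A command-line interface wraps the same stages:

```bash
corticoflow synth --out cohort/ --seed 1
corticoflow preprocess --in cohort/ --out clean/
corticoflow events --in clean/ --out events.csv
corticoflow corr --in clean/ --out corr/
corticoflow run --config pipeline.yaml --out results/ --seed 1
```

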