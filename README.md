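# statewave

Attention waxes and wanes during long psychophysics experiments: moments of
task focus (the ON state) alternate with mind-wandering (OFF), and the only
direct measurements are sparse thought probes on which participants rate
their focus from 1 ("thoughts were anywhere else") to 5 ("totally at the
task").  `statewave` is an analysis pipeline for such experience-sampling
experiments with multichannel neural recordings (MEG/EEG-like).  It

- decodes the attentional state of *every* trial from band-limited neural
  activity, training a one-vs-one SVM per frequency band on the probed
  trials and selecting the band whose predicted rating distribution best
  matches the reported one by the criterion
  **Δ_R = √Σ (R_PL − R_FQ)²** (predicted vs reported rating proportions);
- quantifies the temporal kinetics of the state: whether probes interrupt
  mind-wandering, and how the decoded ON/OFF likelihoods evolve over the
  trials after a probe (correlation with position plus a z-scored composite
  measure with FDR-corrected pairwise tests);
- relates the state to behavior: logistic psychometric fits
  `f(x) = a + (b−a)/(1+e^−(cx+d))` with 75%-correct thresholds,
  sub- (1.5–4.5°) vs supra-threshold (7.5–15°) accuracy, reaction-time
  means and coefficients of variation (100·sd/mean);
- characterizes the evoked responses: the broadband high-frequency
  amplitude (BHA; Hilbert envelope of the 80–150 Hz band), its
  stimulus-responsive channels (z > 3 for ≥ 100 ms), response window
  against a circular-shift surrogate, orientation and ON/OFF contrasts,
  and the C1 component (earliest visual evoked deflection, polarity
  flipping between visual fields) with C1-vs-BHA onset/peak latency
  statistics and time-resolved amplitude coupling.

Real recordings are not required: `statewave.synthetic` generates sessions
with the latent-state, neural and behavioral structure these analyses
assume (drifting 5-level attentional rating with post-probe resets,
state-dependent theta power, tilt- and state-scaled high-frequency bursts,
field-flipping C1 deflections, logistic accuracy and state-dependent
reaction times), retaining the ground truth for recovery testing.

## Worked example

```python
import numpy as np
from statewave import SimulationConfig, generate_session
from statewave.preprocessing import BandBank
from statewave.decoding import pooled_band_decoding

cfg = SimulationConfig(n_trials=150, trial_duration=1.2, pre_stim=0.4,
                       n_channels=3, probe_fraction=0.3, seed=1001)
session = generate_session(cfg)

bank = BandBank([(6.0, 5.1, 6.9), (15.0, 12.75, 17.25),
                 (40.0, 34.0, 46.0), (115.0, 80.0, 150.0)])
results, selected, predictions = pooled_band_decoding(
    [session], bank, grid={"C": [1], "kernel": ["rbf"]}, seed=1)
for r in results:
    print(f"{r.band[0]:6.1f} Hz  delta_R={r.delta_r:.3f}  "
          f"3-class accuracy={r.accuracy_3class:.2f}")
print("selected band:", results[selected].band[0], "Hz")
```

prints

```
   6.0 Hz  delta_R=0.329  3-class accuracy=0.67
  15.0 Hz  delta_R=0.634  3-class accuracy=0.56
  40.0 Hz  delta_R=0.634  3-class accuracy=0.56
 115.0 Hz  delta_R=0.634  3-class accuracy=0.56
selected band: 6.0 Hz
```

The theta band (5.1–6.9 Hz) — the band carrying the state-dependent power
in this synthetic session — has the smallest deviation Δ_R between its
predicted rating distribution and the reported one and the highest grouped
OFF/MID/ON decoding accuracy, so it is selected for the downstream state
analyses.  (The three no-signal bands collapse to majority-class
predictions, hence their identical Δ_R.)

## The analysis

The numbered scripts under `analysis/` run the full study on a simulated
cohort (10 subjects × 220 trials; see `analysis/_config.py`) and write
tables to `results/analysis/`:

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | generate the cohort, summarize ratings/behavior |
| `02_band_decoding.py` | 27-band decoding, Δ_R band selection, trial predictions |
| `03_state_dynamics.py` | probe-interruption ANOVA, ON/OFF evolution, Spearman drift |
| `04_behavior.py` | psychometric thresholds, accuracy and RT by state × level |
| `05_bha_response.py` | BHA response window, orientation/state/flank contrasts |
| `06_c1_bha_latency.py` | C1 vs BHA onsets/peaks, amplitude coupling |

Each script takes `--seed` (default 1); later scripts reuse
`results/analysis/predictions.csv` when `02` has run.

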