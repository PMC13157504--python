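# Methods

`statewave` implements an end-to-end analysis of attentional brain states
(ON / MID / OFF, i.e. task-focused vs. mind-wandering) in an
experience-sampling visual discrimination experiment: decoding the state
from multichannel neural recordings band by band, characterizing how the
state evolves after thought probes, and quantifying its behavioral and
neural correlates (psychometric thresholds, reaction times, the broadband
high-frequency amplitude envelope, and the C1 evoked component).  Because
the package ships no recordings, every analysis is exercised against a
synthetic-session generator whose statistical structure mirrors the study
conditions the analyses assume.  This note documents the models, the
defaults and why they were chosen, and what the synthetic results do and do
not show.

## The synthetic session model

A session is `n_trials` trials of `trial_duration` seconds (default 1.91 s,
the mean trial length of the emulated paradigm), sampled at 500 Hz.  The
stimulus appears `pre_stim` seconds into each trial; a target grating is
tilted by a signed angle from ±{1.5°, 3°, …, 15°} (ten steps of 1.5°).

**Latent attentional state.** Each trial carries a latent rating 1–5
(1 = thoughts elsewhere … 5 = fully on task), grouped as OFF = {1, 2},
MID = {3}, ON = {4, 5}.  The rating follows a first-order Markov drift:
with per-trial hazard `drift_rate` it moves one level toward OFF
(absorbing at 1).  Thought probes are scheduled pseudorandomly on
`probe_fraction` of trials (default 20%), never on adjacent trials; a probe
reports the rating of the trial it follows, and the next trial resets
toward ON (`max(current, draw from {4, 5})`), reflecting that probes
interrupt mind-wandering.  The default hazard 0.45 was calibrated once so
that the stationary rating distribution approximates the reported one in
the emulated study (~21% OFF, ~47% ON); the hazard form itself is the
simplest process that produces a within-seconds ON→OFF relaxation after
each probe.  The generator's MID occupancy (~19%) is lower than the
reported ~31% because MID is a single transit level in this chain; none of
the analyses depend on MID mass.

**Neural components** (injected into the "occipital" half of the channel
array; Gaussian background noise of sd `noise_sd` everywhere):

- *Theta oscillation* at `theta_freq` = 6 Hz with random phase per trial.
  Its power is state-dependent: OFF/ON power ratio `theta_state_gain`
  (default 2), MID at the geometric mean, with a ±3% within-state tweak so
  the five rating levels remain (weakly) separable while the OFF/ON power
  ratio stays within a few percent of the configured gain.
- *Evoked high-frequency burst*: band-limited noise (80–125 Hz) under a
  raised-cosine amplitude window from 50 to 288 ms post-stimulus peaking at
  144 ms.  The carrier band stops at 125 Hz so that the default 500 Hz rate
  exceeds four times the highest synthesized frequency; the burst still
  lies inside the 80–150 Hz analysis band.  The burst amplitude scales
  logistically with |tilt| and multiplicatively with state
  (`bha_gain_by_state`, default OFF 0.7 / MID 0.85 / ON 1.0 — the envelope
  is reduced during mind-wandering).  `bha_state_gain_window` optionally
  restricts the state gain to part of the burst (used to emulate
  rising-flank-only modulation).
- *C1-like deflection*: a raised-cosine bump with onset 49 ms and peak
  68 ms whose polarity flips between upper (negative) and lower (positive)
  visual-field stimulation.
- *Per-subject responsiveness*: one log-normal gain (sd 0.25 in log units)
  multiplies both evoked components of a session.  Subjects with stronger
  evoked responses are stronger in both, which is what produces positive
  C1↔burst amplitude coupling across subjects.

**Behavior.** Accuracy follows the four-parameter logistic
`f(x) = a + (b−a)/(1+exp(−(cx+d)))` of unsigned tilt with state-specific
parameters, calibrated by least squares so that mean sub-threshold
(1.5–4.5°) and supra-threshold (7.5–15°) accuracies and the 75% thresholds
reproduce the emulated state pattern (OFF ≈ 49% sub-threshold but ≈ 78%
supra-threshold; ON ≈ 65% / 84%; thresholds ≈ 5.8–6.6° in all states).
Reaction times are shifted log-normal (shift 0.25 s) with state-specific
mean and sd — slower and more variable in OFF (620 ± 250 ms) than ON
(500 ± 150 ms).  Subject-level jitter perturbs the psychometric midpoint
and the RT mean.

All randomness flows through one seed; per-purpose substreams are spawned
deterministically, so sessions are bitwise reproducible.

**What the generator does not emulate:** sensor geometry and field spread,
1/f background spectra, eye movements and pupil dynamics, learning or
fatigue trends, and any correlation between tilt angle and state.  Passing
recovery tests therefore show that the *pipeline* extracts what was
injected under realistic noise — not that real recordings contain these
effects.

## Preprocessing

Band decomposition uses a geometric progression of center frequencies
(default 27 bands, 3–180 Hz) with symmetric edges at `center·(1 ± 0.15)` —
a total bandwidth of 30% of the center frequency.  Filters are
fourth-order Butterworth applied forward–backward (zero phase; onset
estimates carry no group delay).  Envelopes are Hilbert analytic
amplitudes.  Epochs use half-open windows `[start, end)` relative to the
stimulus (default −0.3 to 0.7 s; the sample at t = 0 is post-stimulus).
Baseline z-scoring is per trial and channel against the −200–0 ms baseline
(mean subtracted, divided by the baseline sample sd; n−1 denominator
everywhere).  Trials whose channel-averaged variance exceeds 4× the mean
variance across trials are rejected and counted in the log, as are RT
outliers (< 100 ms or > 2000 ms, strict bounds) and subjects without
threshold crossings.

## Decoding and the Δ_R band criterion

Features are the per-band epoch time series of all channels, decimated by
an integer factor (stride subsampling) and concatenated to one vector per
trial; columns are z-normalized with parameters fitted on training rows
only.  By default the *Hilbert envelope* of each band is decoded rather
than the raw filtered waveform: band amplitude carries the state
information, and envelope features are invariant to oscillation phase,
which stabilizes decoding at the trial counts used here (raw-waveform
features remain available via `feature_kind="filtered"`).

The classifier is a one-vs-one SVM (RBF kernel, `γ = 1/(N_features·σ)`)
with stratified 5-fold cross-validated grid search on an 80% training
split and accuracy reported on the held-out 20%.  Class weights default to
natural priors: re-weighting toward rare rating levels flattens the
predicted-label marginal of a *signal-free* band, which lets it mimic the
reported rating distribution and corrupts band selection (see below).
Training-fold augmentation (Gaussian-noise copies, window shifts,
phase-shifted subsampling that reuses the points discarded by decimation)
is implemented and leakage-safe — augmented copies are grouped with their
source trial across folds — but is off by default at these data sizes.

Band selection uses Δ_R = √Σ(R_PL − R_FQ)², the root of the summed squared
differences between the predicted rating distribution (unlabeled trials)
and the reported one (probed trials).  The band minimizing Δ_R is
selected; ties break by higher decoding accuracy, then lower center
frequency (logged).  On default synthetic sessions the theta band wins and
grouped (OFF/MID/ON) decoding accuracy exceeds both the majority-class
baseline and the 80–150 Hz band's accuracy.

## State dynamics

*Probe interruption*: per subject, OFF and ON likelihoods at probed trials
(reported) and the first trial after each probe (decoded) enter a 2-way
ANOVA (trial type × state); the main and interaction F are referred to a
surrogate built by recomputing the post-probe likelihoods from as many
randomly chosen trials as there are post-probe trials (1000 runs).

*Evolution*: decoded ON and OFF likelihoods at positions FQ+1 … FQ+25
(~2 s per step, 50 s span; probed trials are excluded — they carry
reported labels).  Group-level Pearson r of each series against position
is referred to a within-subject label-shuffle surrogate.  A per-subject
composite (z-scored ON series averaged with the sign-reversed z-scored OFF
series) is compared FQ+1 vs FQ+N with paired t-tests whose p come from the
same shuffle, FDR-corrected across the pairwise family.  Positions without
data are missing, not zero; subjects are omitted, never imputed.  The
supplementary Spearman variant correlates probe ratings with their
distance from the most recent ON report, per subject, and tests the
coefficients against zero.

## Statistics core

Every empirical null uses the add-one convention
`p = (1 + #{null ≥ observed}) / (1 + n_iter)`, so p is never zero, and is
reproducible bit-for-bit given a seed.  For two-group permutation tests
with ≤ 10⁴ distinct assignments the null is enumerated exactly and p is
the exact permutation p.  Circular-shift surrogates rotate each subject's
series by an independent uniform offset with wrap-around — preserving each
subject's power spectrum exactly while destroying event alignment — and
recompute the group statistic per iteration.  ANOVA F values come from
classical sums of squares (balanced designs for two-way layouts; infinite
F with zero within-cell variance is returned flagged); surrogate p values
accompany the parametric ones.  Benjamini–Hochberg FDR is applied within
each analysis family (the time points of one contrast; one set of pairwise
comparisons).  Tests are two-tailed unless the hypothesis is explicitly
directed (supra > sub orientation contrast; ON > OFF flank contrasts).

## Neural responses

Stimulus-responsive channels must hold z > 3 (two-sided Gaussian tail
0.0027) for ≥ 100 ms post-stimulus, with strict sample contiguity.  The
group response window comes from pointwise circular-shift p values, FDR
across time, reporting the widest significant post-stimulus run (onset,
offset, peak).  The ON vs OFF time course uses pointwise paired t against
a within-subject label-permutation (sign-flip) null, FDR across time; the
flank contrasts average the rising (50–122 ms) and falling (122–288 ms)
burst segments before testing.  The C1 is collapsed across visual fields
by sign-flipping the upper-field response and averaging; onsets are first
post-stimulus z > 3 crossings and peaks the maximum inside the
supra-threshold run (never the global argmax unless no run exists).
The C1→burst amplitude coupling is the time-resolved Pearson r of the
per-subject C1 peak amplitude with the envelope, against a null that
reassigns the C1 values to subjects at the time of the maximum observed
correlation; the critical value is the 99th percentile of that null.

## Problem sizes and numerical choices

The analysis scripts and the acceptance script simulate 10 subjects × 220
trials (4 channels) with 500-iteration surrogates; recovery and
calibration tests use 8–20 subjects or 30–300 trials per replicate with
199-iteration surrogates, 50–100 replicates per claim.  These sizes were
chosen as the smallest at which the injected effects are reliably
recoverable; they are an order of magnitude below the emulated study
(20–23 subjects × ~1100–1300 trials, 102+ sensors), so absolute statistic
values (F, t, z) are not comparable to full-scale values even though
directions, latencies and proportions are.  Psychometric fits are
least-squares on per-angle mean accuracy (`scipy.optimize.curve_fit`,
deterministic given the initial point); thresholds are finite only when
75% lies strictly between the fitted asymptotes.  Sessions serialize to a
binary array container plus JSON sidecar and CSV trial tables (lossless);
epochs can be exported to FIF for interoperability.

## Known limitations

- With white background noise, envelope baselines are better behaved than
  in real 1/f recordings; artifact-rejection rates on synthetic data are
  near zero rather than the few percent typical of real sessions.
- The OFF psychometric curve has a shallow span (upper asymptote ≈ 0.78),
  so its fitted 75% threshold is poorly conditioned and can drift well
  above the generating value even when the fit is good elsewhere; the ON
  and MID thresholds are stable.
- Group onset latencies of the envelope (first z > 3 crossing of the
  subject-mean series) are systematically later than the burst-template
  onset at small channel counts, because the criterion requires the group
  mean to clear the threshold, not the first detectable energy.
- The drift chain under-represents the MID state (see above).
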