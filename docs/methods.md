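# Methods

This note documents the processing model, its parameters and defaults, the
synthetic-data generator, and the numerical/design choices made where the
procedure was genuinely open.

## Signal model and preprocessing

A trial is a pair of synchronized streams: raw sEMG in µV and elbow joint
angle (ROM) in degrees, nominally 60 s at 1024 Hz. Preprocessing is a fixed
chain:

* **Band-pass**: Butterworth of design order 4, passband 20–450 Hz, applied
  forward–backward (`sosfiltfilt`). Zero-phase filtering is chosen because the
  envelope must stay time-aligned with the ROM signal used for segmentation;
  the group delay of a causal filter would bias burst timing relative to the
  cycles. Applying the filter to data that was already band-passed upstream
  (some acquisition systems filter on-device) is safe: the passband is only
  re-shaped, not shifted.
* **Rectification**: elementwise absolute value.
* **RMS envelope**: root mean square over *consecutive, non-overlapping*
  0.25-s windows, giving a 4 Hz envelope (240 samples per 60-s trial). The
  non-overlapping reading is the only one consistent with a decimated 4 Hz
  effective rate — a sliding window with unit stride would keep the raw rate.
  A trailing partial window is discarded rather than zero-padded, which would
  bias the final sample downward.

## Activation threshold (baseline-noise correction)

Resting instrumentation noise leaves a positive floor under the envelope. The
correction estimates a muscle-specific activation threshold from quiet signal:

1. **Movement onset** from the ROM trace: first time the lightly smoothed
   (0.1-s moving average) rectified angular speed exceeds 5°/s continuously
   for 0.5 s. The speed is rectified *before* smoothing so the brief zero
   crossings at each movement reversal (twice per cycle at 60 bpm) do not
   break a sustained run. ROM is the only kinematic channel recorded, so a
   speed criterion is the natural task-independent choice. If the movement is
   already under way at t = 0 the onset is 0 with a warning; a trace whose
   speed never sustains the threshold is an error.
2. **Noise window**: the first-occurring minimum of the envelope before onset,
   with a 60-envelope-sample window (15 s at 4 Hz) centred on it, clipped at
   the signal bounds **and at the onset**. The onset clip matters: with a
   short quiescent lead-in the centred window would otherwise reach into the
   movement period and the "noise" statistics would swallow genuine bursts.
   Clipping keeps the window a resting-noise window, which is the point of the
   procedure. (`clip_noise_window_at_onset=False` restores bound-only
   clipping.)
3. **Threshold**: window mean + 3 × population SD (ddof = 0). The threshold is
   subtracted from the entire envelope; samples at or below it are set to 0
   but kept on the timeline so cycle windows stay aligned. For Gaussian-like
   noise this retains well under 2 % of noise-only samples.

The window is defined on the 4 Hz envelope by default. The exact correction
is translation-invariant (adding a constant shifts the threshold by exactly
that constant) and fully scale-invariant together with the rest of the chain:
multiplying a trial's raw EMG by any positive gain scales envelope, threshold
and RMS identically, leaving post/pre ratios unchanged to floating-point
precision — the property that makes the ratio statistic gain-free.

## Cycle segmentation and the trial statistic

Cycles are anchored at successive peak-flexion maxima of the ROM trace
(`find_peaks` with minimum spacing of half the nominal cycle period and
prominence ≥ max(25 % of the ROM range, 2°); the absolute 2° floor rejects
noise-only traces whose relative prominences would otherwise pass). Cycle *i*
is the half-open interval between peaks *i* and *i+1*. A valley anchor is
available and differs only by phase.

From *n* detected cycles the analysis keeps the 10 consecutive cycles starting
at `floor((n-10)/2)` — centred on the middle of the trial, resolving the
even/odd ambiguity toward the earlier block, and invariant to symmetric
padding. The per-trial statistic is the RMS of the corrected envelope over the
union of the selected intervals, **pooling all on-timeline samples including
thresholded zeros** (a true energy measure over the task window); an
active-samples-only variant is exposed via `rms_mode="active"` because the
retained-values phrasing of the correction admits both readings. Each post
trial's RMS is divided by the same session's baseline RMS to give the ratio.

## Statistical families

* **Intragroup** (per session): mixed model `log R_it = β_t + b_i + ε_it`
  with one fixed effect per follow-up point (no global intercept), a random
  intercept per participant, fitted by REML (statsmodels `MixedLM`). On the
  log scale "ratio = 1" becomes "β_t = 0" and multiplicative subject effects
  become additive; group means are still reported on the raw ratio scale.
  Each β_t is tested with a Wald z statistic; a raw-ratio-scale variant
  (coefficients tested against 1) ships as `scale="ratio"`, and neither
  variant is claimed to be "the" canonical one. Degenerate inputs (constant
  response, zero SE) map to the boundary p-values (p = 1 when the estimate
  equals the null). Unbalanced/missing rows are handled by the likelihood.
* **Intergroup** (per follow-up point): paired differences fmv − control over
  participants with both sessions (≥ 3 required). Shapiro–Wilk at α = 0.05
  gates between the paired t-test (df = n−1) and the two-sided Wilcoxon
  signed-rank test (zero differences dropped); all-zero differences are
  degenerate and reported as p = 1 with a warning.
* **Multiplicity**: Benjamini–Hochberg step-up, implemented in-repo
  (`adjusted_(i) = min_{j≥i} m·p_(j)/j`, capped at 1) and verified against a
  brute-force oracle and statsmodels. Families are the 7 intragroup tests per
  session and the 7 intergroup tests.

Wald z (rather than a degrees-of-freedom-corrected t) is the default contrast
test; at 30 participants the anticonservatism is small (per-test size ≈ 0.06)
and the measured null family discovery rate stays within Monte-Carlo error of
the nominal 0.05 — the null-fidelity test checks exactly this.

## Synthetic study generator

`vibemg.simulate` produces complete crossover studies with known ground truth.
Per trial: a 3-s quiescent lead-in, then a sinusoidal ROM at 60 bpm
(90° peak-to-peak over a 10° resting angle) plus low-pass-filtered angle noise
(SD 0.15°, 3 Hz — filtered so its derivative does not defeat the onset
detector the way white angle noise would). The EMG is band-limited
(20–450 Hz) Gaussian carrier noise modulated by a raised-cosine burst centred
on mid-extension of each cycle (the triceps is the elbow extensor), occupying
40 % of the cycle, over additive white noise (SD 8 µV) present throughout.
Burst gain is `80 µV · exp(subject) · exp(trial) · ratio` with subject SD 0.3
(log scale, drawn once per participant and shared across both sessions) and
trial jitter SD 0.1. The default fmv ratio profile is
`{0: 0.84, 5: 0.80, 10: 0.86, 15: 0.84, 20: 0.85, 25: 0.97, 30: 0.93}` —
attenuation for ~20 minutes, then recovery — and control is 1 everywhere.
One seeded generator drives every draw in a fixed order, so studies are
byte-reproducible.

Two deliberate gaps between the generator and real data:

* Because the subject amplitude effect is shared by all trials of a session it
  cancels exactly in the post/pre ratio; synthetic ratio SDs (~0.15) are
  therefore smaller than the ~0.3 observed in real recordings, where electrode
  repositioning, fatigue and attention add trial-level variance the ratio does
  not cancel. The pipeline-recovery tests consequently over-state power
  relative to real data; they validate correctness of the chain, not field
  power.
* For dispersion-realistic Monte-Carlo work the ratio-level companion
  generator `simulate_ratio_table` draws
  `log R = log r_true + b_i + e` with b SD 0.3 and residual SD 0.2, chosen
  once so total ratio dispersion lands near the 0.3–0.35 seen in practice.
  It exercises the statistical layer only.

The generator also does not emulate: motor-unit structure (the carrier is
Gaussian), electromechanical delay, cadence drift or fatigue trends within a
trial, and the biceps channel (only the antagonist is analysed).

A small mean bias is expected in pipeline ratio estimates: the noise-derived
threshold is subtracted from both pre and post envelopes, so attenuated trials
lose proportionally more (≈ −0.01 to −0.02 at the default 80 µV bursts,
shrinking as burst amplitude grows). This is a property of the thresholding
procedure itself, visible only because the generator provides ground truth.

## Problem sizes and tolerances

Monte-Carlo checks in the test suite run 20 full-pipeline replicate studies
(n = 30 each) for parameter recovery and significance patterns (recovery
tolerance ±0.05 on replicate-averaged means), and 200 ratio-level replicates
for null fidelity (family discovery rate ≤ 0.05 + 2 × MC standard error).
`scripts/acceptance.py` runs one full study plus 100 null replicates.
Numerical comparisons of exact algebraic identities (BH vs. oracle, RMS vs.
brute force, scale invariance) are asserted at machine precision or 1e-9
relative.

## Known limitations

* Onset detection assumes some quiescent lead-in; trials that start
  mid-movement fall back to onset 0, where the threshold stage then fails for
  want of a pre-onset segment and the trial is excluded via QC (by design).
* With fewer than ~15 s of lead-in the 60-point noise window is truncated at
  the onset, so threshold estimates use fewer samples and are noisier.
* The Wald-z contrasts are mildly anticonservative at small n; a
  Satterthwaite-type correction is a possible extension.
* Statistical conclusions transfer to real recordings only to the extent the
  generator's variance structure matches them (see above).
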