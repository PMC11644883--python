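# Methods

This note documents the models implemented in `uef`, the defaults and the
reasoning behind them, what the synthetic data does and does not emulate,
and the numerical choices that affect results.

## The UEF motor model

A motor trial is 20 s of wrist angular velocity ω(t) in deg/s sampled at
100 Hz during repeated maximal-effort elbow flexion/extension. Analysis
proceeds in three stages.

**Filtering.** All filters are Butterworth filters applied zero-phase
(forward–backward with `sosfiltfilt`), so per-cycle extrema are not shifted
or skewed by phase distortion; the price is that the effective amplitude
response is the squared single-pass magnitude. Two filters are involved:

* a first-order high-pass for drift/DC removal (`highpass_cutoff`). The
  conventional cutoff for this protocol is 2.5 Hz and that is the default
  of `uef.motor.highpass`; however a first-order high-pass is shallow, and
  zero-phase application at 2.5 Hz has amplitude gain
  `|H|² = 1/(1+(fc/f)²) ≈ 0.27` at a 1.5 Hz fundamental — it would erase a
  narrowband flexion signal rather than clean it. Real maximal-effort
  flexion bursts are broadband and survive such a filter far better than a
  smooth synthetic lobe does. Because the synthetic trials used throughout
  testing place their fundamentals at 0.7–1.3 Hz, the pipeline
  configuration (`RunConfig.highpass_cutoff`) defaults to **0.25 Hz**:
  enough to remove DC and the generator's 0.1 Hz drift while costing <3%
  in the motion band. The cutoff is fully configurable and `None` disables
  the stage; closed-form validation of the measurement operations is done
  with the filter off.
* a second-order 10 Hz low-pass (`lowpass_cutoff`) applied before
  segmentation, range extraction and differentiation. Per-cycle max−min is
  an extreme-value statistic: with white noise of SD 5% of the lobe
  amplitude, raw ranges inflate by ~10%; band-limiting to 10 Hz reduces
  this to <1% while leaving a 2 Hz fundamental attenuated by <0.1%.

**Segmentation.** Cycles are delimited by alternating zero crossings of
the filtered velocity: one positive (flexion) lobe plus the following
negative (extension) lobe per cycle. Lobes shorter than half of
`min_cycle_ms` (default 200 ms) are treated as debounce chatter and merged
into their neighbours; partial lobes at the record edges are dropped
(<60% of the median lobe length); cycles with velocity range below
`min_range_frac` (default 0.1) of the median range are discarded. Fewer
than three surviving cycles raises "trial unusable".

**Parameters.** All range-based parameters are computed per cycle and then
averaged, consistent with the per-cycle definition of the moment. The
moment is the inertial term `I·|α|_max` only: a gravity torque would
require an elbow-angle zero reference that a gyroscope-only recording does
not provide. `I` defaults to standard body-segment proportions
(forearm+hand mass = 2.2% of body mass; radius of gyration about the
elbow = 0.827 × forearm length = 0.827 × 0.146 × height), overridable
directly; the weighted condition adds the hand-held mass (default 0.5 kg)
as a point mass at a configurable radius (default 0.25 m). Angular
acceleration is the central difference of the 10 Hz low-passed velocity,
in rad/s².

**Naming switch.** Published descriptions of this protocol are
inconsistent about which of the two variability measures is called "speed
reduction" and which "speed variability": the printed definitions label
the CV as speed reduction and the last-vs-first change as speed
variability, while the reported statistics (a sign-crossing "reduction"
near 0 ± 10% and a positive "variability" near 8 ± 4%) fit the opposite
assignment. Both mappings are implemented behind
`compute_motor_params(naming="table1" | "swapped")`; the unambiguous
underlying quantities (`cv_pct`, `decline_pct`) are always reported
alongside. No claim is made that either mapping matches the original
scoring model.

**Frailty score.** The published frailty model's coefficients are not
public, so the score here is a documented surrogate: each sub-parameter is
normalised linearly between a *fit* anchor (score contribution 0) and a
*frail* anchor (contribution 1), clipped, and combined with non-negative
weights summing to one; the score is 100 × the weighted sum. Default
anchors span roughly the cohort mean ± 2 SD of each sub-parameter in a
mixed weighted/unweighted protocol (speed 1400→0 deg/s, moment
3.9→0.6 Nm, flexibility 166→44 deg, CV 0→17.2%, decline +19.8→−19.4%),
with equal weights of 0.2. The score is monotone in each sub-parameter in
the physiologically expected direction and bounded in [0, 100] by
construction.

## The heart-rate model

**Beat detection** is the classical Pan–Tompkins chain: 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration, then
sequential dual adaptive thresholds (running signal/noise peak estimates
with 0.125/0.875 updates), a 200 ms refractory period, T-wave rejection by
slope comparison for candidates within 360 ms of the last beat, and
search-back at 1.66× the running RR average against half the threshold.
Band edges and window length follow the canonical published algorithm.
The filters are applied zero-phase, which keeps the integrated peak near
the R wave; beat times are refined to the raw-ECG maximum within ±75 ms.

**Task-window detection** thresholds the 1 s moving RMS of the
median-centred accelerometer magnitude at the quiescent level plus
`k` = 6 robust standard deviations (MAD-based — the task occupies a
minority of the record, so median statistics estimate the quiet floor).
The coarse supra-threshold run is then edge-refined at 1/√2 of the plateau
RMS, the crossing that coincides with the true edge of a variance step
seen through a centred RMS window. A run outside 20 s ± 50% raises "task
not found". Baseline and post windows of 60 s abut the task and are
truncated to the available record with a warning.

**RR → HR.** Intervals outside [0.25 s, 3 s] are discarded (physiological
bounds; prevents division blow-ups), instantaneous HR = 60/RR is placed at
interval midpoints, and a centred rolling median over `smooth_beats` = 5
beats suppresses single-beat artifacts before any extremum extraction
(1 disables; window means are insensitive to this setting to within 1%).
Whether the original analyses took extrema on raw or smoothed HR is not
stated anywhere; smoothed extrema are the default here because a single
ectopic-like interval would otherwise define `hr_increase`.

**Window parameters.** Means are time-weighted (trapezoidal) averages;
`hr_increase` and `hr_decrease` are extremum-vs-extremum percentages with
the sign convention that a recovery below the task peak is negative.
Smartwatch per-second HR streams skip detection and enter these window
statistics directly, mirroring how consumer wearables expose HR.

## Agreement statistics

ICC is computed from the two-way ANOVA mean squares of the n-subjects ×
2-devices table: ICC(2,1) = (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE)),
ICC(3,1) = (MSR−MSE)/(MSR+(k−1)MSE), k = 2. ICC(2,1) — two-way random
effects, absolute agreement, single measures — is the default, the
standard choice when two fixed devices must agree in absolute value; the
consistency form is available for sensitivity analysis, and every report
records which form was used. The implementation is verified in the test
suite against a brute-force sums-of-squares oracle (≤1e−10 over hundreds
of random tables) and against pingouin.

Differences are watch minus reference throughout. Pearson R² uses the
t-distribution with n−2 df for its two-sided p; the paired t-test is
two-sided. Degenerate tables (identical devices) return documented
conventions instead of erroring: p = 1 for all-zero differences, the
smallest positive float for a constant non-zero difference, ICC = 1 for a
zero-variance table — each flagged. No multiple-testing correction is
applied (α = 0.05 per comparison, matching the analysis design this
package mirrors).

## The synthetic cohort: what it emulates, and what it does not

No participant recordings from this protocol are publicly available, so
the generators emulate the study conditions with known ground truth:

* **Flexion trials** are alternating half-sine lobes — smooth, integrable
  in closed form (excursion = A/(πf)), with realistic zero crossings for
  segmentation. Amplitude declines linearly across cycles (exact on the
  first/last-5 s window means of the noise-free schedule) with
  multiplicative Gaussian cycle jitter; 0.1 Hz drift and white noise are
  added. Cohort bounds: unweighted condition A ∈ [250, 450] deg/s at
  0.9–1.3 Hz with decline ∈ [−12, +4]%; weighted condition (0.5 kg)
  A ∈ [90, 250] deg/s at 0.7–1.1 Hz with decline ∈ [−25, −5]% — the
  weighted arm emulating the slow, fatiguing, frail end of the spectrum.
  These bounds place cohort-mean speed, flexibility and moment inside the
  plausible ranges reported for this protocol (≈655 ± 372 deg/s,
  ≈105 ± 30 deg, ≈2.2 ± 0.8 Nm). They are an *emulation* of plausible
  spread, not an estimate of any real cohort's distribution.
* **Device overlays**: reference sensor ≈ transparent (2 deg/s noise);
  smartwatch with gain 1.04, +2 deg/s offset, 6 deg/s noise, 5 ms clock
  jitter — small discrepancies of the kind wrist devices show.
* **HR profiles**: constant baseline (65–95 BPM), linear rise over the
  first half of the 20 s task to baseline × (1 + Δ) with Δ ∈ [20, 55]%,
  then a plateau, then exponential recovery with τ ∈ [15, 35] s; Gaussian
  RR jitter of 5–20 ms. The ramp-plateau shape (rather than a full-task
  ramp) reflects the fast HR rise under sudden exertion and makes the task
  maximum a recoverable feature rather than a single instant. All five
  parameters have closed forms recorded as truth.
* **ECG** is template-based — Gaussian QRS (1 mV, 10 ms SD) with smaller
  P/T waves, 0.25 Hz baseline wander, optional white noise at a given
  SNR — sufficient to exercise every stage of Pan–Tompkins, with no claim
  of morphological realism (no arrhythmia, no electrode artifacts).
* **Watch HR stream**: trailing moving average (default 10 s) of the true
  instantaneous HR, delayed 5 s, with 2.5 BPM noise that is **4× larger
  inside the task window** — optical HR degrades while the wrist moves.
  This motion term is what drives the qualitative reproduction of the
  two-device pattern: window means average the noise away and keep
  ICC ≥ 0.9, while the extremum-based dynamic parameters absorb both the
  smoothing attenuation and the in-task noise and fall to ICC ≈ 0.4–0.7.

Consequently, passing tests demonstrate that the *analysis pipeline*
recovers known signal properties and that the *agreement machinery*
behaves correctly under controlled degradation. They do not validate the
pipeline against real gyroscope noise spectra, real ECG morphology, real
PPG firmware behaviour, or real inter-subject physiology.

## Numerical and design choices

* Zero-phase filtering everywhere a filter touches data used for extrema.
* Axis selection for triaxial trials: maximum-variance channel (the
  flexion axis dominates during UEF); ties resolve to the first axis with
  a warning; an all-constant recording is an error.
* Trial-to-subject aggregation: trials averaged within subject ×
  condition, each subject × condition forming one agreement unit
  (`RunConfig.aggregate = "per_condition_mean"`); per-trial analysis is
  available (`"per_trial"`). How the original six trials were reduced is
  not stated anywhere, so both modes exist.
* Determinism: every generator is a pure function of its parameter object
  including the seed (NumPy `default_rng`); the pipeline is deterministic
  for fixed inputs, and full simulated runs are byte-identical across
  reruns with the same seed. CSV export uses a pinned dialect (UTF-8,
  comma, '.' decimal, `%.10g`).
* Per-subject failures in a cohort run are logged and excluded, never
  fatal; agreement for a component is skipped (with a log line) if fewer
  than three complete pairs remain.
* Problem sizes in the validation suite — 20-seed recovery medians,
  20 × 140 s ECGs for detector quality, 200 random tables for the ICC
  oracle, 34-subject cohorts for the pattern checks — were chosen to make
  median-based claims stable at interactive runtimes.

## Known limitations

* The frailty surrogate is calibrated to plausible anchor ranges, not to
  the original regression; absolute scores are comparable only within
  this package.
* The inertial moment omits gravity torque and assumes a rigid
  forearm+hand segment with population-average proportions.
* The Pan–Tompkins implementation is tuned for single-channel adult ECG
  at ≥250 Hz; it has no arrhythmia handling beyond physiological RR
  bounds.
* Bland–Altman limits assume approximately constant difference variance
  across the measurement range (no regression-based or repeated-measures
  extension).
* The PPG emulation outputs an HR stream, not an optical waveform; its
  smoothing, lag and motion-noise constants are stylised, chosen to
  reproduce the qualitative steady-vs-dynamic agreement pattern rather
  than any specific device's firmware.
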