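# Methods

This note records the models, parameter choices and numerical conventions
behind `ergoload`, and what the synthetic-data checks do and do not
establish about field data.

## Signals and synchronization

A measurement day consists of four streams: sEMG (4 muscle channels + a
trigger channel, 1024 Hz, mV), upper-back IMU and thigh IMU (3-axis
acceleration in g + 3-axis angular rate in deg/s, 100 Hz), and a heart-rate
series in bpm (1 Hz in the synthetic data; real monitors sample the
underlying ECG faster but the pipeline only consumes beats-per-minute
values). All segment annotations are half-open intervals in seconds on the
EMG clock.

Synchronization landmarks are detected as (a) upward crossings of 50 % of
the nominal 2 mV trigger amplitude with a 1 s debounce, and (b) bursts of
integrated gyroscope displacement exceeding 60° within a 1 s sliding
window — robust to the nominal 95° solenoid rotation while ignoring the
same displacement accumulated slowly as postural drift. Because the sliding
window flags a run that *contains* the burst rather than its onset, the
event time is refined to the leading edge of the peak angular rate (first
sample before the peak where the rate falls under 10 % of it); without this
refinement the offset estimate is biased by most of a window length.
Matched landmark pairs (chronological order) give the stream→EMG clock map:
offset only with one pair, offset plus linear drift (least squares) with
two or more, mirroring the pre- and post-day synchronization procedure.
Drift between two daily landmarks is assumed linear; crystal-oscillator
drift over a working day is a few tens of ppm, well inside that regime.

## EMG processing

* Band-pass 10–500 Hz, 4th-order Butterworth applied forward–backward
  (zero phase), per-channel mean removal, optional 50 Hz notch. The chain
  follows common surface-EMG practice; the sEMG device's own passband is
  wider, so this only removes offset/motion artifact and out-of-band noise.
* RMS windows: 500 ms with 20 % overlap, i.e. step =
  `round(0.8 · 0.5 s · fs)` samples — 410 samples at 1024 Hz (rounding half
  up); the trailing partial window is dropped.
* MVE = max RMS window across the (≤3) MVC trials of a muscle group.
* Reference threshold = 90th percentile of reference-lift RMS windows,
  using the linear-interpolation quantile (the conventional estimator; the
  choice matters little at ~150 windows per lift segment).
* Base thresholds: `ref100` averages the per-session reference P90s over
  the sessions present (morning and afternoon when both were recorded; a
  single session is used as-is and flagged, since field days can end
  early); `ref150 = 1.5·ref100`; `mvc50 = 0.5·mean(session MVEs)`. All
  MVC sessions annotated are averaged into the MVE by default.

All of these are positively homogeneous of degree 1 in the channel gain,
so event labels are invariant to per-channel amplification — the property
that makes between-day comparisons of event *counts* meaningful without
absolute calibration of the electrodes.

## Posture

The gravity direction is taken from the accelerometer low-passed at 2 Hz
(2nd-order Butterworth, zero phase); no gyro fusion is used, matching
accelerometer-inclinometry practice (the gyro serves only the sync
landmark). The N-pose calibration stores the unit mean accelerometer
vector over the standing segment plus an orthonormal device triad built
from the device's anterior axis (configurable `forward_hint`) projected
orthogonally to gravity; a mean norm deviating from 1 g by more than
0.3 g raises a movement-during-calibration error.

For a filtered gravity estimate **a**: total inclination is the angle to
the calibration gravity; `forward = atan2(a·f̂, a·ĝ)` (flexion positive)
and `sideways = |atan2(a·ŝ, a·ĝ)|` (left/right symmetric, as the threshold
decay is). Total inclination always bounds both components. Samples whose
filtered norm leaves [0.7, 1.3] g are flagged invalid rather than dropped.
The decomposition is covariant under remounting: rotating calibration
data, work data and the forward-axis convention together leaves the angle
series unchanged.

Steps are counted on the thigh stream as peaks of the 0.5–3 Hz band-passed
acceleration norm with prominence ≥ 0.2 g and a 0.3 s refractory period,
normalized to steps/hour by the work-interval length. Heart rate is the
mean over samples inside [30, 220] bpm; a day with more than half of its
samples excluded carries a quality warning.

## Event detection

Epochs are 10 s, nonoverlapping, aligned to the start of the annotated
work interval; a trailing partial epoch is dropped. Per epoch and muscle,
the P90 of the RMS windows *starting* inside the epoch (the same
500 ms/20 % parameters as calibration); an epoch is invalid when any
muscle has fewer than 5 windows or more than half of its inclination
samples are flagged. The posture summary is the P90 of within-epoch
samples — mirroring the EMG summary and robust to spikes — computed with
the *upper order statistic* (`method="higher"`), so that a full second of
deep flexion inside an epoch registers at its full angle rather than being
interpolated away at the 10 % boundary.

Labeling rules, per threshold mode:

* two-muscle rule — at least 2 of the 4 muscles strictly above their
  *base* threshold (the inclination modification never applies here);
* modified-ES rule — either erector spinae strictly above
  `T_mod(base, fwd, side) = base·min(1 − ½·min(|fwd|,90)/90,
  1 − ½·min(|side|,30)/30)`.

Ties are non-events; invalid epochs are never events and are reported
separately. Both rules apply in every mode (including the exploratory
`ref150`/`mvc50` modes) by default; a `two_muscle_rule_only` switch
provides the stricter exploratory variant, since the plain-language
description of the exploratory analyses is ambiguous on this point. Event
epochs are exported as a CSV log (start time, muscles over threshold,
posture, rule fired) for manual lookup against workplace video.

## Synthetic data

The day generator renders the study conditions: pre-day sync landmark;
3 MVC trials per muscle group (2.5 s ramp to MVE, 3 s hold, 30 s rests);
10 reference-lift cycles (6 s cycle, 4 s active at the reference
amplitude); 15 s N-pose; the work interval with scripted overload
episodes aligned to the 10 s grid; optional afternoon calibration; post-day
landmark. sEMG is amplitude-modulated Gaussian noise band-limited to
20–450 Hz with the scripted RMS envelope — the detector consumes only RMS,
so no motor-unit-level realism is attempted. Default amplitudes (per
muscle): baseline 0.015 mV, reference lift 0.12 mV, MVE 0.6 mV — resting
activity around 1–3 % of maximal and the 20 kg lift around 20 % of
maximal, typical surface-EMG magnitudes for these muscles. IMU streams
carry the gravity vector of the scripted inclination trace plus 0.02 g
noise (back), a 2 Hz gait impact train during walking intervals (thigh;
60 s of walking every 600 s of work by default), a configurable clock
offset (3.2 s) and drift (20 ppm) against the EMG clock, and the solenoid
rotations. Heart rate is a 92 bpm baseline plus load-linked increments,
clipped to [40, 200] bpm.

Every scripted episode's ground-truth label per mode is computed from the
scenario's *nominal* amplitudes and the exact labeling rule, so pipeline
recovery can be scored epoch by epoch. Episodes at exactly 1.5× the
`ref100` threshold sit deliberately *on* the `ref150` threshold: their
`ref150` truth is "no event" (strict inequality) while measured amplitudes
fluctuate around it, which is why only subset ordering — never the
`ref150` count — is a recovery criterion.

What passing these checks shows: the chain of synchronization,
calibration, feature extraction and labeling implements the stated rules
exactly and recovers known envelopes under realistic noise. What it cannot
show: behaviour under electrode lift-off, sweat artifacts, motion
contamination coherent across channels, non-stationary baselines, or
postures outside the two-angle trunk model — field validity rests on the
original laboratory validation of the measurement chain, not on these
simulations.

The trial generator draws log event counts from the mixed model itself
(fixed arm/time/interaction effects, independent Gaussian cluster and
subject intercepts and residual; defaults 0.2/0.4/0.5 on the log scale,
i.e. a cluster ICC of ~0.09), with gang sizes 4–6 in 8 gangs per arm
(~80 workers, matching the recruited cohort of 80 in 15 gangs) and
missing-at-random follow-up dropout (10 %/20 %). Covariates (age, working
duration, mean heart rate, steps, strength; gender constant male) are
generated but carry zero effects by default so parameter recovery is
clean; nonzero effects can be injected.

## Trial statistics

* Outcome transform: `log(count + 1)`; the offset is recorded in output
  metadata. Counts of zero occur on quiet or short days, so plain `log`
  would be undefined; at typical counts (~e⁵) the offset is negligible.
* Model: REML linear mixed model via statsmodels `MixedLM`, random
  intercept for cluster plus an individual-within-cluster variance
  component; fixed effects arm, time, arm×time. The *adjusted* variant is
  fitted on follow-up occasions only, conditioning on the subject's
  baseline outcome plus age, gender, measuring duration, mean heart rate,
  steps and strength (constant covariates — e.g. gender in an all-male
  cohort — are dropped with a log message). Intention to treat is
  likelihood-based: all subjects contribute whatever occasions they have,
  no imputation.
* Inference: Wald z statistics on the REML fit. Kenward-Roger (or
  Satterthwaite) small-sample degrees of freedom are not available in this
  ecosystem's mixed-model implementation; the result object records the
  method tag, and the package's calibration evidence is simulation-based —
  at ~200 subjects in 30 clusters the 95 % CI coverage of the interaction
  estimate and the type-I error of the joint interaction Wald test are
  verified to be near nominal in the test suite (200 and 500 replicates
  respectively). With very few clusters Wald z inference is expected to be
  anti-conservative; that regime is not certified.
* A fit whose variance components pin at zero is flagged `singular`, not
  raised: degenerate (no-noise) data then reproduces the OLS solution.
* Contrasts are least-squares-mean differences read off the coefficient
  vector: between-group at each follow-up = arm effect + interaction term;
  within-group changes = time effect (+ interaction for the intervention
  arm).
* Sample size: smallest per-group n whose exact two-sample two-sided
  noncentral-t power reaches the target (df = 2n−2, noncentrality
  `(δ/σ)·√(n/2)`), iterated over n rather than normal-approximated — for a
  20 % reduction with 20 % SD at α = 0.05 and power 0.80 this gives 17 per
  group, and the cluster design effect `ceil(n·1.5)` gives 26.
* Baseline comparisons: two-sample t-tests, pooled variance by default
  (Welch behind a flag — the original analysis software's default is the
  pooled form).
* Exact r×c test: full enumeration of contingency tables with the observed
  margins under the multivariate hypergeometric null; p = sum of
  probabilities of tables no more probable than the observed one (relative
  tie tolerance 1e−9). Bounded to 3×3 and total ≤ 500; beyond that the
  error message suggests Monte-Carlo approximation. Enumerated
  distributions are cached per margin class (margins canonicalized up to
  row/column permutation and transpose, which leave the probability
  multiset invariant).

## Problem sizes

Default verification scales, chosen to exercise the full pipeline at desk
scale: a 2 h simulated working day (720 epochs, 50 planted episodes) for
end-to-end recovery; a 20–30 min day for invariance and on-disk demos;
~200 subjects / 30 clusters with 200 recovery and 500 null replicates for
mixed-model calibration; exhaustive enumeration of all 2×2 and 2×3 tables
with total ≤ 40 (≈9.6 million tables) against an independent vectorized
oracle for the exact test.

## Known limitations

* Trunk posture is two angles from one accelerometer; no heading, no
  segment kinematics, no arm elevation.
* The modified threshold applies to the erector spinae only, as specified
  by the detection rule; trapezius thresholds are never posture-modified.
* Wald-z mixed-model inference (see above) rather than Kenward-Roger.
* The synthetic sEMG validates amplitude logic, not spectral or
  physiological realism.
* Step counting is a simple peak counter tuned to the synthetic gait
  train; against real thigh accelerometry it would need re-validation.
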