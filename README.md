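# ergoload

Detection of **events of excessive physical workload** from synchronized
wearable recordings of a working day — surface EMG of the neck/shoulder and
low-back muscles plus inertial sensing of trunk posture — and the
cluster-randomized-trial statistics used to evaluate whether an ergonomic
intervention changes how often such events occur.

The package is aimed at occupational-biomechanics researchers who run field
measurements on workers in physically demanding jobs (the motivating
setting is construction work, where crews operate as gangs and trials must
randomize at gang level). Because raw field recordings of this kind are
rarely shareable, a first-class synthetic-data module generates complete
measurement days and trial outcome tables with known ground truth, so every
stage of the pipeline is testable end to end.

## The measurement model

Four bipolar sEMG channels (upper trapezius left/right: `TrpL`/`TrpR`,
erector spinae left/right: `ESL`/`ESR`) are sampled at 1024 Hz; triaxial
accelerometer + gyroscope units sit on the upper back (T1–T2) and thigh at
100 Hz; a heart-rate series summarizes overall activity. Streams are
synchronized by hardware landmarks fired before and after the working day —
a 2 mV pulse on a spare EMG channel and a fast ~95° solenoid rotation of
the IMUs — from which a per-stream clock offset and linear drift are fitted.

**Calibration.** EMG amplitude is RMS over 500 ms windows with 20 % overlap.
Each muscle gets two normalization anchors:

* MVE — maximum voluntary electrical activity: the largest RMS window over
  up to 3 maximal voluntary contractions (MVC),
* the 90th percentile of RMS during 10 standardized reference lifts
  (20 kg box, floor to a 73 cm table).

Base event thresholds per muscle *m*: `ref100(m)` = mean of the morning and
afternoon reference-lift P90; `ref150(m) = 1.5·ref100(m)`;
`mvc50(m) = 0.5·MVE(m)`.

**Event detection.** Working time is tiled into nonoverlapping 10 s epochs.
Per epoch: the P90 of each muscle's RMS windows, and the P90 of forward and
sideways trunk inclination (accelerometer tilt relative to the gravity
direction captured in a 15 s neutral standing pose). An epoch is an *event*
when

1. at least two of the four muscles exceed their base threshold
   (strict inequality), **or**
2. either erector spinae channel exceeds its inclination-modified
   threshold

```
T_mod(base, f, s) = base · min( 1 − ½·min(|f|, 90°)/90°,
                                1 − ½·min(|s|, 30°)/30° )   ∈ [base/2, base]
```

i.e. the low-back threshold decays linearly to half at 90° forward or 30°
sideways inclination and is constant beyond — the same sEMG amplitude
counts as a higher load when the trunk is flexed.

**Trial analysis.** The per-day event count is the primary outcome of a
two-arm cluster-randomized trial (gangs as clusters; baseline plus two
follow-ups). Counts are log(x+1)-transformed and fitted by a REML linear
mixed model with fixed effects arm, time, arm×time (plus baseline-value and
measurement-day covariates in the adjusted variant) and random intercepts
for cluster and individual-within-cluster, analyzed by intention to treat.
The sample-size arithmetic behind such a trial — an exact noncentral-*t*
iteration plus a cluster design-effect inflation — is also provided.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_day.py     # signal files + ground truth
python analysis/02_detect_events.py    # sync -> calibrate -> detect
python analysis/03_trial_analysis.py   # simulate + fit the cluster trial
python analysis/04_power.py            # sample-size arithmetic
```

`02_detect_events.py` prints, for a 30-minute working excerpt with 12
scripted overload epochs at 1.5× the reference threshold:

```
epochs analyzed: 180 (180 valid)
  ref100: 12 events (24.00/h)
  ref150: 10 events (20.00/h)
  mvc50: 0 events (0.00/h)
ref100 recovery: 12/12 ground-truth epochs, 0 spurious
steps 363, mean HR 93.1 bpm
sync offsets: back 3.200 s, thigh 3.200 s
```

All 12 planted epochs are recovered with no false positives under the
pre-planned `ref100` mode; the exploratory `ref150` mode (thresholds 50 %
higher, the planted amplitude sitting exactly on them) fires on a subset,
and `mvc50` on none — at half of maximal activation these episodes are not
extreme. The recovered clock offset matches the simulated 3.2 s exactly.
`03_trial_analysis.py` fits both mixed models on a simulated ~80-worker
trial with a true intervention-by-time effect of −0.3 on the log count and
prints the between-group least-squares-mean differences with 95 % CIs and
the interaction p-value; `04_power.py` prints `n per group: 17; with design
effect 1.5: 26`.

The same machinery is exposed as a CLI (`ergoload simulate-day`,
`simulate-trial`, `calibrate`, `detect`, `analyze`, `power`) over a
documented on-disk format: one delimited text file per stream plus a JSON
sidecar (`fs`, `channels`, `units`, `site`, `t0`), and one JSON annotation
file per session listing segments (`mvc_trapezius`, `mvc_erector`,
`reference_lift`, `npose`, `sync`, `work`) as half-open `[start_s, end_s)`
intervals on the EMG clock.

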