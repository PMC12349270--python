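# Methods

## Problem and model

The pipeline classifies 3 s windows of body-worn accelerometer data as
*aggressive movement* (violent shaking of an infant surrogate) or
*non-aggressive movement* (light shaking or ordinary caregiving). The
classifier is deliberately minimal — a binary CART decision tree with Gini
impurity capped at depth 2, one tree per sensor position — because the
intended deployment is continuous on-device inference on a low-power
wearable, where interpretability and a tiny memory/compute footprint matter
more than the last point of accuracy.

All modeling happens on the acceleration norm
`sqrt(ax² + ay² + az²)`, never on individual axes. Since rotations preserve
Euclidean length, every downstream feature is invariant to sensor mounting
orientation; this is asserted to 1e-9 by property tests that rotate raw
axes with random proper rotations.

## Windowing and labeling

* Window length 3 s, adjacent windows share 1 s, so starts advance by
  2 s. "Overlap" is read as shared content between neighbors, giving
  `floor((n - w)/s) + 1` complete windows (w = 300 samples, s = 200 at
  100 Hz); partial tail windows are dropped. A 15 s task therefore yields
  7 windows.
* Ground truth comes from annotation events (label, start, end, error
  flag). A window takes the label of the event class covering the most of
  its samples; *light* and *daily care* both map to non-aggressive; ties go
  to non-aggressive (the conservative direction for the rare class); a
  window with under 50 % of its samples inside any event is left unlabeled
  and excluded from modeling (counted in the log). Events flagged as
  operator errors are ignored.
* Sample membership: sample *i* (time *i/fs*) is inside an event when
  `start ≤ i/fs < end`; indices are 0-based half-open throughout.

## Features (per window, on the norm)

mean, standard deviation (population convention, ÷n), 10th/50th/95th
percentiles (linear interpolation; the 50th is the median), min, max,
skewness (Fisher–Pearson standardized third moment, no bias correction),
excess kurtosis (normal → 0, no bias correction), RMS, average frequency,
entropy. Stored as 12 fields because the median and 50th percentile are the
same quantity reported once each in summaries.

"Average frequency" and "entropy" are implemented spectrally: the
power-weighted mean frequency (spectral centroid) and the Shannon entropy
in bits of the normalized one-sided periodogram, both of the mean-removed
norm with the DC bin excluded. Spectral entropy is scale-invariant and
standard in human-activity-recognition feature sets; a histogram entropy of
amplitudes would be the main alternative reading. Beyond mean removal no
filtering, detrending or outlier handling is applied anywhere — the
detector must work on raw streams without added latency.

Degenerate conventions (chosen to keep the tree free of NaNs): a
zero-variance window has skewness = kurtosis = 0, and a window with zero
oscillatory power has centroid = entropy = 0.

## Decision tree

* Split search is exhaustive: every feature, every midpoint between
  consecutive distinct sorted values; the split maximizing the weighted
  Gini decrease wins. Ties break toward the lower feature index, then the
  smaller threshold. Near-ties (within 1e-12) are re-compared in exact
  rational arithmetic from the integer cell counts, so the fitted tree is a
  pure function of the data and never depends on floating-point noise in
  the impurity values. Tests verify equality with an independent
  brute-force enumeration (also exact-rational) on hundreds of random
  instances, and against scikit-learn's CART as a second, external
  cross-check.
* Recursion stops at depth 2 (default), purity, fewer than
  `min_samples_split` = 2 rows, or no strictly improving split. Leaves
  predict their majority class; leaf ties predict aggressive, favoring
  sensitivity in a safety application.
* Evaluation uses a stratified random 70/30 split at the segment level
  (per-class counts preserved to ±1 row). Because adjacent windows share
  1 s of signal, a segment-level split lets correlated windows from one
  recording land on both sides; a participant-grouped split mode is
  provided for leakage-free estimates, with the caveat that group
  stratification is then only approximate. The segment-level split is the
  default as the conventional evaluation procedure for this design.
* Feature importance is the sample-weighted Gini decrease per feature,
  normalized to sum to 1; a single-leaf tree returns an all-zero vector
  flagged unnormalized.
* Metrics treat aggressive as the positive class: sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP). Zero-denominator ratios are reported as NaN
  with the metric named in a flag, never silently 0. Values are stored at
  full precision; the reporting layer rounds half-up to two decimals.

## Synthetic data: what it emulates and what it does not

The generator reproduces the structure of the study protocol: 8
participants × 18 fifteen-second tasks × 6 sensor positions at 100 Hz,
with 7 high-risk tasks (ids 2, 4, 6, 7, 8, 10, 13), 6 light shaking tasks
and 5 daily-care tasks — 144 task executions, 56 aggressive and 88 not,
864 recordings per session.

Motion model: sensed specific force = (randomly oriented, per-recording
constant) gravity vector + sinusoid along the task's shake axis with
per-cycle ±10 % amplitude/frequency jitter + white Gaussian noise
(σ = 0.05 g). Default ranges, drawn once per (participant, task) so all six
sensors see the same underlying motion:

| class              | amplitude (g) | frequency (Hz) |
|--------------------|---------------|----------------|
| aggressive shaking | 3–6           | 3–5            |
| light shaking      | 0.3–1.0       | 1–2            |
| daily care         | 0.1–0.5       | 0.3–1          |

Per-position attenuation captures that limbs see trunk-shaking damped
(head/chest 1.0, arms 0.9, legs 0.8) and that arm-swing tasks invert this
(arms 1.0, elsewhere 0.6). Two tasks get dedicated patterns: the playful
throw (free-fall spans where the norm drops toward 0, then a capped catch
impulse) and burping (gentle rocking plus ~0.5 g patting impulses).

A 2.5 g norm threshold stands in for the training doll's warning LEDs. The
amplitude ranges guarantee, by construction and after worst-case jitter and
axis orientation, that aggressive tasks peak above it and benign tasks stay
below it at the motion's full-amplitude sensor site (head for trunk tasks,
arm for arm-swing tasks); `MotionParams.validate` enforces this
analytically and tests confirm it over hundreds of simulated tasks. All
magnitudes are generator parameters, not measured values: no public
recordings of the target activity exist, so none of these numbers should be
read as physical measurements.

Consequences for interpretation: the synthetic classes are separable by a
single magnitude threshold, so the depth-2 trees typically reach perfect
held-out scores and concentrate importance on the norm's mean or RMS. The
end-to-end acceptance bar (accuracy ≥ 0.90 and sensitivity ≥ 0.80 at every
position) is an artifact-level guarantee that the pipeline recovers the
construction — it says nothing about performance on real handling data,
where inter-class overlap, sensor artifacts, transient non-task motion and
annotation noise all exist and none are modeled. The generator also does
not model biomechanics (no head-injury criteria, no joint dynamics) or
gyroscope channels (the analysis uses acceleration only).

## Determinism and numerics

Every source of randomness flows from one integer seed: simulation uses a
`SeedSequence` spawned per (participant, task) with per-sensor child
streams, and each position's train/test split seeds from
`(seed, 1, position index)`. Fitting itself is deterministic. Recordings
and feature tables are written with `%.17g`, and files are re-read with
round-trip float parsing, so disk round-trips are exact and the file-driven
CLI chain (`simulate → segment → features → train → evaluate`) reproduces
the in-memory pipeline byte for byte; two runs with the same config are
byte-identical. Timestamps are stored explicitly and validated for
uniformity (1e-9 s tolerance) so corrupt captures fail loudly at read time.

Problem sizes: the default simulated session (864 recordings, 1008 windows
per position) simulates, featurizes and trains in a few seconds on one CPU;
tests use a 2-participant, 2-position variant of the full 18-task protocol
where session scale is not itself under test.

## Known limitations

* The synthetic separability means absolute metric values on simulated data
  are optimistic; only the pipeline mechanics, invariances and bookkeeping
  transfer to real data.
* The maximum-overlap labeling rule is a deterministic stand-in for manual
  video review; boundary windows around event transitions are where it
  would most plausibly disagree with a human annotator.
* Config validation accepts only the built-in 18-task protocol (optionally
  subset by task id, participants or positions); fully custom task tables
  must be constructed programmatically via `TaskSpec`/`Protocol`.
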