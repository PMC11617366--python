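# Methods

This note documents the models, conventions and design choices behind
`collarsense`, and what the synthetic benchmark does and does not show.

## Temperature pipeline

Raw infrared skin readings are filtered with a **centered rolling median**
of `round(window_s × rate)` samples, forced to the nearest odd integer so
the window is symmetric and the median unambiguous. Edges use truncated
(shrinking) windows rather than padding — no fabricated temperatures enter
the output. A centered (rather than trailing) window was chosen for zero
phase lag; a trailing variant only shifts the output and is not exposed as
an option. At the default 1 Hz temperature rate a 1-s window is a single
sample (identity); sensors with faster frame rates get a genuinely
smoothing window automatically, which is the point of specifying the window
in seconds.

Quantiles are empirical with linear interpolation between order statistics
(the common "type 7" rule). Skin-vs-rectal error is
`rectal_baseline − smoothed skin`, with the rectal reference modeled as a
per-animal constant (time-varying rectal series are out of scope); the
median and IQR of that error distribution are reported. No skin→core
correction algorithm is applied.

## Feature extraction

Windows of `length_s` (default 10 s) tile the stream with configurable
overlap. A window is labeled by the behaviour covering a **strict
majority** of its duration; exact ties or insufficient coverage leave it
unlabeled (retained, excluded from training) — this avoids arbitrary
tie-breaks contaminating the training set.

Per channel: F1 mean, F2 population variance (1/n), F3 RMS, F4 Fisher
skewness g₁, F5 excess kurtosis g₂ (both mapped to 0 when the variance is
0), F6 time-domain energy Σx², F8 integral of absolute value Σ|x|·dt
(sampling-rate-invariant). Seven features × 9 channels = 63 values,
flattened channel-major. Useful identities hold exactly in real
arithmetic and to 1e-9 in floating point: F3² = F1² + F2 and F6 = n·F3².
An optional eighth per-channel feature slot exists as a config hook but is
deliberately left empty: no defined F7 is invented.

## Behaviour classification

Six scikit-learn estimators stand behind the module surface, with
defaults: KNN k=5; Gaussian naive Bayes; MLP with one hidden layer of 64
units, ≤500 iterations; RBF-SVM with C=10, gamma="scale"; a single
cost-complexity-pruned decision tree (the "binary classification tree");
random forest with 200 trees. Scale-sensitive models (KNN, SVM, MLP) are
wrapped with per-feature z-scoring fitted on training rows only; tree
models are not. All randomized fits take an explicit seed.

Evaluation pools held-out predictions across **grouped-by-animal folds**
(leave-one-animal-out by default) before computing one-vs-rest TP/FN/FP
counts, so reported scores reflect generalisation to unseen animals and no
animal straddles the train/test boundary. Sensitivity and precision are
percentages; a class never predicted has undefined precision and is
excluded from the macro precision rather than scored 0, matching how an
"Average" row over present classes is normally formed. `macro_average` is
a plain unweighted mean, and `compare_classifiers` reuses identical folds
across algorithms so the comparison is paired.

## Step counting

A **binary RBF-SVM** (same feature representation, 1-s non-overlapping
windows by default) detects walking windows. Training rows are capped at a
balanced 3000 per class via a seeded subsample so kernel training stays
tractable on multi-hour cohorts.

Counting rule: a 1-s window cannot resolve individual steps at gait rates
above 1 Hz, and one-count-per-window would systematically undercount by
the factor `gait_rate × window_s`. The default rule therefore uses the SVM
only to delimit *where* walking happens (maximal runs of positive windows,
optionally merged across short gaps) and counts **one step per gait cycle**
within each run: the fore–aft acceleration is mean-detrended, lightly
smoothed (3 samples), and cycles are counted as hysteresis mean-crossings
with threshold ±0.5·RMS of the run — scale-free, and insensitive to sensor
noise in the partial windows at run edges. `per_window` and `per_run`
rules remain available for diagnostic use. Accuracy
`100·(1 − |I − A|/A)` treats over- and under-counting symmetrically and is
undefined for animals that never walked (excluded from aggregates, listed
in reports).

## Synthetic data generator

The generator emulates housed cattle wearing a neck collar:

* **Schedules** come from a semi-Markov chain over the five sustained
  behaviours: exponential dwell times with means feeding/grazing 300 s,
  walking 90 s, lying rest 600 s, standing rest 240 s (floored at 10 s —
  shorter bouts are rare in practice and would be unresolvable at 10-s
  windows), successor states from a row-stochastic matrix, and every
  stand↔lie change bridged by a 3-s transition class. The initial state is
  drawn from the embedded chain's stationary distribution.
* **IMU**: per sample, gravity orientation for the posture plus a
  deterministic behaviour component plus Gaussian noise. Standing-type
  postures put gravity on +z, lying on +y; grazing pitches the collar 40°
  (head down), feeding 15°; transitions ramp the pitch linearly. Walking
  adds a 1.5-Hz, 0.4-g fore–aft sinusoid (with a half-amplitude vertical
  component) and emits one ground-truth step per cycle; grazing/feeding add
  a 0.35-Hz head-bob (0.12 g; feeding 1.5× with a lateral sway so the two
  head-down behaviours are separable). Accelerometer noise is 0.02 g at
  rest and 0.05 g otherwise; gyroscope noise 0.5 °/s; the magnetometer is a
  constant heading plus noise (no field physics). The IMU rate defaults to
  20 Hz — typical for collar accelerometry and giving 200-sample 10-s
  windows; it is a config knob, not an inferred constant.
* **Temperature**: (38.3 − 1.1) °C baseline + 0.1 °C sinusoidal drift
  (1-h period) + AR(1) noise (φ=0.9, stationary sd 0.15 °C) + Poisson
  artifact spikes (0.5/min, 1–3 samples, ±1 °C), at 1 Hz.
* **Reproducibility**: one root seed per animal; the schedule, IMU and
  temperature use fixed-offset child seeds so components can be regenerated
  independently. Everything is bit-reproducible for a fixed seed.

What this does **not** emulate: biomechanically realistic gait, individual
variation in posture or gait frequency, magnetometer physics, weather or
circadian effects on skin temperature, fever, or annotation noise in the
labels. Passing tests therefore demonstrate that the pipeline's machinery
(featurisation, training, scoring, counting) is correct and that the
method recovers known structure under its own assumptions — not that the
same accuracy would be achieved on field recordings, whose behaviours are
less stereotyped.

## Numerical and degenerate-input choices

* Zero-variance windows map skewness/kurtosis to 0 rather than NaN.
* Non-uniform timestamps beyond 1e-6 relative tolerance, empty traces,
  single-class training sets, overlapping label intervals and unknown
  behaviour names are rejected with descriptive errors.
* Windows shorter than the stream's end are dropped (no partial windows);
  a stream shorter than one window yields zero events with a warning.
* JSON artifacts are written with sorted keys and a config hash that
  excludes the output path, so identical (config, seed) runs are
  byte-identical wherever they are written.

## Problem sizes

The test suite exercises cohorts of up to 6 animals × 30 min for
classification and 2–3 animals × 30–60 min for detector training; the
benchmark script runs the full 10-evaluation-animal × 3-h study with a
3-animal training cohort. These sizes give thousands of labeled windows
per run and stable (<0.1 percentage point across seeds) benchmark values.
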