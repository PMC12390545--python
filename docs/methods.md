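# Methods

This note documents the models behind `gaitsense`, the defaults that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open.

## Synthetic gait generator

### Magnitude signal

The calibration target is the acceleration-*magnitude* signal
‖a‖ = √(AccX² + AccY² + AccZ²), gravity included (the pocket mean of
12.1 m/s² exceeds g because the phone swings with the thigh). Per
condition the generator targets (mean, std) of (12.1, 0.60) pocket,
(10.0, 0.28) look, (9.9, 0.27) text, all in m/s².

The magnitude variance is budgeted as 55 % step-frequency fundamental,
10 % second harmonic, 15 % slow pace drift, 20 % white sensor noise:

```
m(t) = mean* + A₁ sin(2πft + φ₁) + A₂ sin(4πft + φ₂) + s·OU(t)
```

where `OU` is a stationary Ornstein–Uhlenbeck process with a 10 s
correlation time (people speed up and slow down over a session), and the
OU amplitude is scaled by the exact AR(1) finite-sample variance factor so
the *within-trace* sample variance hits its budget share (a finite trace's
sample variance of a correlated process is biased low because the trace
mean absorbs low-frequency power).

The signal vector is assembled in the world frame — small fore–aft and
lateral oscillations at the step frequency and its half, with the vertical
component absorbing the rest of the magnitude — then rotated into the
device frame through the condition's carrying orientation (pocket: gravity
on the device X axis, as a phone upright in a trouser pocket reads;
look/text: tilted screen-up postures). Rotation preserves the norm, so the
calibration survives exactly.

Sensor imperfections are added in the device frame: isotropic white noise
carrying the 20 % variance share, and a constant per-trace bias
(`acc_bias_std` = 0.12 m/s² per axis) modeling an uncalibrated
accelerometer offset. The construction mean is corrected by
`(σ_noise² + σ_bias²)/mean` for the second-order norm inflation these
perpendicular components cause, so the empirical magnitude mean converges
to the target. `magnitude_mean_std()` returns the predicted spread of
per-trace means (bias projection + OU time-average wander); calibration
tests use `3σ/√n_seeds` of that model as their Monte-Carlo tolerance,
since the i.i.d. formula `σ/√n_samples` does not apply to an
autocorrelated signal.

Gyroscope channels oscillate at the step frequency with a condition-level
RMS (0.45 rad/s pocket — the phone swings; ~0.1 rad/s look/text — the
phone is held); the magnetometer is a rotated constant field plus jitter.
Step cadence defaults: 1.8 Hz pocket, 1.6 Hz under distraction.

### Ground truth and GPS

Walks are straight lines at the subject's effective speed (pocket
1.4 m/s, reduced under distraction by the subject's
`distraction_speed_drop`); ground truth distance is exactly speed ×
duration. GPS fixes sample the true path at 1 Hz, perturbed by a
stationary Gauss–Markov error with per-axis marginal std 3 m (the typical
open-sky error) and a 60 s correlation time: receiver error drifts slowly
while consecutive fixes stay mutually consistent, which matches real
receivers — independent 3 m jumps at 1 Hz would imply ~4 m fix-to-fix
displacements no handset shows. Setting `corr_time_s=0` recovers
uncorrelated noise. Positions are mapped to latitude/longitude by a local
equirectangular projection about the trace origin; for sub-kilometer paths
the projection error is far below the GPS noise.

### Subjects, traits, cohorts

`generate_cohort` draws per-subject traits from hyper-distributions:
walking-speed scale (lognormal 8 %), gait-variability scale (lognormal
25 %), baseline magnitude offset (N(0, 0.35) m/s²), a *distraction-gap*
offset (N(0, 1.0) m/s², clipped at ±2 m/s²) shifting only the look/text
magnitude mean, cadence offset, and gyro scale. The distraction-gap
spread reflects that how strongly a person's acceleration drops when
distracted varies a lot between people — which is what makes
cross-subject (LOSO) classification genuinely harder than personalized
classification on this cohort.

E/I trait modulation applies only under distraction, where trait
differences in gait are reported: introverts get a larger speed drop
(15–30 % vs 3–10 %), a stronger variability reduction (×0.85 vs ×1.0,
between-subject Cohen's d ≈ 0.6 on accelerometer features), and markedly
steadier gyro/magnetometer activity (×0.65/×0.70 vs ×1.0, d ≈ 2). The
asymmetry is deliberate: accelerometer-only trait classification should be
weak and multi-sensor classification strong. Because pocket windows carry
no trait signal at all, window-level E/I accuracy on the default cohort is
capped near 0.83 even for a perfect classifier. `trait_modulation=False`
removes every systematic E/I difference for null calibration.

What the generator does **not** emulate: turning, stopping, stairs and
terrain; step-level biomechanics (heel strikes, double support); device
orientation drift within a trace; urban-canyon GPS outages; real
inter-device hardware differences. Passing tests therefore demonstrate
the pipeline's correctness and the qualitative condition/trait/protocol
relationships, not field accuracy on real recordings.

## Kalman fusion

A linear Kalman filter (the printed state-space model is linear, so
nothing is gained by an extended variant): planar constant-velocity state
`[x, vx, y, vy]`, accelerometer control input through `B`, position-only
GPS updates, with `Q = 0.1·I₄`, `R = 5.01·I₂` (interpreted in m², ≈2.24 m
per axis), `P₀ = 300·I₄`, `Δt = 0.01 s`. The control input is the
device-frame accelerometer rotated to world through the static per-trace
mount rotation (emitted by the generator in the trace metadata) minus the
gravity vector; vertical dynamics are not modeled. GPS fixes are applied
at the propagation step nearest the fix time (exact halves round down).
The filter warm-starts position and velocity from the first two fixes —
with `P₀ = 300·I` the filter would converge anyway, but the
constant-velocity model would otherwise spend the first seconds learning
the walking speed and systematically undershoot short walks.

**Distance accounting.** Walked distance accumulates the motion-model
displacement of each prediction step. A measurement update corrects the
state estimate — and thereby where later steps integrate from — but its
correction jump is not itself walked distance. Counting update jumps
would add the fix-to-fix measurement jitter to the path length on every
fix, which both inflates the estimate and reverses the expected
precision ordering between fine and coarse propagation steps.

Evaluation: MAE and RMSE on the cumulative-distance series (truth
interpolated to the estimate's time base) and the total-distance error
rate `|pred − true|/true`. On straight-line walks with temporally
correlated GPS error, summing raw fix-to-fix chords is nearly unbiased —
straight paths have no corners to cut — so the fusion-beats-GPS-only
property is only meaningful (and is tested) under uncorrelated fix noise,
where chord summation inflates badly and the filter's smoothing at the
coarser step wins by an order of magnitude. The fusion-beats-dead-
reckoning property holds under default noise: the accelerometer bias makes
open-loop double integration diverge quadratically.

## Features and classifiers

Each uniform-grid trace is cut into non-overlapping 1 s windows (trailing
partial dropped, half-open boundaries). Per window: mean and max of the
magnitude (`avg_speed`, `max_speed` — field-conventional names; the units
are m/s² since they are magnitude statistics, not integrated velocities),
the population std of consecutive magnitude differences (`std_speed`),
mean and max absolute jerk (|Δ‖a‖|/Δt), and mean/std of the gyro and
magnetometer vector norms (orientation-invariant by construction). The
`accel_only` subset is the first three; `multi_sensor` is all nine.

Classifier settings: random forest with 100 trees and unrestricted depth;
XGBoost with log-loss and a fixed seed (optional grid over n_estimators,
max_depth, learning_rate, subsample, colsample_bytree); Gini decision
tree, unrestricted; k-NN with k ∈ 3–10, Euclidean, uniform weights; RBF
SVM with C ∈ [0.1, 100], scaled gamma; L2 logistic regression (liblinear)
with C ∈ [0.1, 100]. Scale-sensitive models are standardized in-pipeline.
Where a range is specified, it is searched by seeded stratified 3-fold CV
on training rows only; the packaged defaults use fixed mid-range values so
desk-scale runs stay fast. Labels are binary-encoded internally
(`abnormal` = look/text is the positive class — the application cares
about catching distraction).

AUC is computed by an explicit threshold sweep with tie collapsing and
trapezoidal integration, which is algebraically the Mann–Whitney U
statistic normalized by n₊·n₋; the test suite verifies that equality to
1e-12 against an independent implementation. Aggregates are unweighted
means over subjects (or folds); confusion counts are summed.

Protocols: personalized (per-subject stratified 80/20), LOSO (each fold
holds out one subject entirely, including from any hyperparameter
search), and E/I (subject-grouped k-fold on trait labels, run for both
feature subsets). Every protocol asserts train/test row disjointness at
fit time.

## Alert machine

Per-second labels feed a counter: `abnormal` increments, `normal` resets
to zero ("continuous" detection means an uninterrupted run), and reaching
five raises an alert. An active alert swallows incoming labels — alerts
never stack — through its display window of 7 s inclusive of the expiry
instant; counting re-arms with the first window strictly after expiry or
dismissal, so after a raise at t the earliest second raise is t + 12.
Dismissal is allowed at any time and logs a warning when no alert is
active. The machine is validated exhaustively against an independent
windowed formulation over all 2¹² label sequences of length 12.

## Problem sizes and numerics

Default experiment sizes mirror the study design: 21 subjects × 3
conditions × 5 repetitions of 90 s at 100 Hz (28 350 windows); generator
calibration checks average 20 seeded traces per condition; the
sampling-interval comparison averages 20 seeded 60 s walks. The full test
suite runs in well under a minute of compute for the physics and a few
minutes including the classification properties. Numerical choices:
covariances re-symmetrized after every update and property-tested to stay
positive semi-definite to −1e-9; resampling is exact (1e-12) on already
uniform grids; CSV round-trips print shortest-repr floats and parse them
in round-trip precision; GPS ties round down; degenerate inputs (single
sample windows, single-class training sets, fewer than two subjects)
raise typed errors rather than producing silent results.

## Known limitations

Field-scale accuracies from real participants are outside what synthetic
data can certify; this package demonstrates directions and rankings
(pocket vs look/text statistics, personalized ≥ LOSO, ensembles ≥ linear
models, multi-sensor > accelerometer-only for traits) rather than absolute
field numbers. The straight-line walking assumption makes GPS-only chord
summation artificially strong as a distance baseline. The E/I experiment
treats the trait as a fixed binary label; nothing here validates the
underlying personality instrument.
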