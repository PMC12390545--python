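# gaitsense

Detecting **distracted walking** — using a phone while on the move — from
nothing but the handset's own sensors. `gaitsense` is a Python library and
CLI that implements the full desk-scale stack for this problem:

1. **Synthetic gait simulation** — seeded smartphone-IMU traces
   (accelerometer, gyroscope, magnetometer at 100 Hz, plus GPS fixes) for
   three carrying conditions: *pocket* (normal gait), *look* (screen
   viewing) and *text* (messaging), with per-subject heterogeneity and an
   extraversion/introversion trait modulator.
2. **Kalman sensor fusion** — walked-distance estimation with a planar
   constant-velocity filter, accelerometer control input and GPS position
   corrections.
3. **Windowed gait features** — per-1-second statistics of the
   acceleration magnitude ‖a‖ = √(AccX² + AccY² + AccZ²), jerk, and
   gyroscope/magnetometer norms.
4. **Classification harness** — six classifiers (random forest, XGBoost,
   decision tree, k-NN, RBF-SVM, logistic regression) evaluated
   personalized (within-subject), leave-one-subject-out (LOSO), and on
   E/I trait labels with subject-grouped cross-validation.
5. **Real-time alerting** — a debouncing state machine: five consecutive
   abnormal 1-second windows raise an alert that stays visible 7 s or
   until dismissed.

## The models

**Distance fusion.** The walker state is `X = [x, vx, y, vy]` with the
constant-velocity transition and acceleration control matrices

```
A = [[1, Δt, 0, 0],        B = [[Δt²/2, 0 ],
     [0, 1,  0, 0],             [Δt,    0 ],
     [0, 0,  1, Δt],            [0, Δt²/2],
     [0, 0,  0, 1 ]]            [0,    Δt]]
```

and a position-only measurement `H`. Defaults are `Q = 0.1·I₄`,
`R = 5.01·I₂`, `P₀ = 300·I₄`, `Δt = 0.01 s` — process noise modeling soft
continuous human motion, measurement noise the few-meter error of open-sky
GPS, and a large initial covariance for fast initial alignment.

**Condition signatures.** The generator is calibrated so the
acceleration-magnitude signal (gravity included) reproduces the study
conditions: pocket 12.1 ± 0.60 m/s², look 10.0 ± 0.28 m/s², text
9.9 ± 0.27 m/s² — an ≈2.2-fold drop in gait variability when the phone is
held still in front of the walker. Those first- and second-moment
signatures are exactly what the classifiers exploit.

## Worked example

```python
import numpy as np
from gaitsense import (default_profiles, generate_trace, generate_gps,
                       run_fusion, FusionConfig, evaluate_distance, magnitude)
from gaitsense.synthetic_gait import DEFAULT_ORIGIN

profiles = default_profiles()
trace, truth = generate_trace(profiles["pocket"], duration_s=90, seed=7)
m = magnitude(trace.acc)
print(f"pocket magnitude: mean={m.mean():.2f} m/s^2, std={m.std():.2f} m/s^2")

trace.gps = generate_gps(truth, DEFAULT_ORIGIN, rate_hz=1.0,
                         noise_std_m=3.0, seed=7)
result = run_fusion(trace, config=FusionConfig(dt=0.01))
mae, rmse, err = evaluate_distance(result, truth)
print(f"walked {truth.total_distance:.1f} m, estimated {result.distance_m:.1f} m "
      f"(MAE {mae:.1f} m, error rate {err*100:.1f}%)")
```

prints

```
pocket magnitude: mean=11.89 m/s^2, std=0.60 m/s^2
walked 126.0 m, estimated 131.7 m (MAE 2.7 m, error rate 4.5%)
```

The 90-second pocket walk lands on the condition's calibrated magnitude
statistics (the per-trace mean wanders a couple tenths of m/s² because of
the simulated accelerometer bias and slow pace drift), and fusing the
noisy accelerometer with 1 Hz GPS recovers the 126 m walked distance to
within a few percent.

The same pipeline from a shell:

```bash
gaitsense simulate --out cohort/ --subjects 21 --reps 5 --seed 0
gaitsense extract  --traces cohort/ --out features.csv
gaitsense evaluate --features features.csv --model xgboost --protocol personalized
gaitsense pipeline --out report.json --subjects 6 --reps 2 --seed 0
```

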