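"""Seeded synthetic smartphone-IMU gait traces per carrying condition.

Three carrying conditions are emulated: ``pocket`` (phone in trouser
pocket, normal gait), ``look`` (screen viewing while walking) and ``text``
(messaging while walking).  The calibration targets are the statistics of
the acceleration-*magnitude* signal (gravity included): mean 12.1 m/s² with
standard deviation 0.60 m/s² in the pocket, dropping to 10.0 ± 0.28 and
9.9 ± 0.27 m/s² under screen viewing and texting — an ≈2.2-fold reduction
in gait variability when the walker holds the phone still in front of them.

The generator synthesizes the oscillatory part of the magnitude signal as

    m(t) = mean + A₁·sin(2πft) + A₂·sin(4πft)

with the variance budget split 70 % fundamental / 10 % second harmonic /
20 % white sensor noise, embeds m(t) in a world-frame vector (small
horizontal gait oscillations, the vertical component absorbing the rest of
the magnitude), rotates it into the device frame through the condition's
carrying orientation, and finally adds the sensor imperfections: isotropic
per-axis white noise carrying the 20 % noise share of the magnitude
variance, and a small constant per-trace bias (an uncalibrated
accelerometer offset).  Rotation preserves the norm and the construction
mean is corrected for the small noise-induced norm inflation, so the
device-frame accelerometer magnitude converges to the target statistics.

Subject heterogeneity (per-subject speed, variability, baseline magnitude,
cadence and gyro scaling) and an extraversion/introversion trait modulator
(introverts slow down more and stabilize gyro/magnetometer activity under
distraction) make personalized-vs-generalized and trait-classification
experiments meaningful on purely synthetic cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .fusion import local_to_latlon
from .sensor_io import CONDITIONS, GpsTrack, SensorTrace, TraceMeta

__all__ = [
    "ConditionProfile",
    "SubjectSpec",
    "GroundTruth",
    "CohortConfig",
    "DEFAULT_ORIGIN",
    "default_profiles",
    "generate_trace",
    "generate_gps",
    "draw_subject",
    "generate_cohort",
]

#: default geographic origin of synthetic walks (degrees lat, lon)
DEFAULT_ORIGIN = (37.45, 126.65)

# variance split of the magnitude signal: step-frequency fundamental,
# second harmonic, slow pace drift (OU, ~10 s), white sensor noise
_VAR_FUNDAMENTAL = 0.55
_VAR_HARMONIC = 0.10
_VAR_SLOW = 0.15
_VAR_NOISE = 0.20
_SLOW_TAU_S = 10.0


@dataclass
class ConditionProfile:
    """Generative parameters for one carrying condition.

    ``orientation`` is a quaternion (x, y, z, w) rotating world (ENU)
    vectors into the device frame; gravity therefore lands on the device
    axis the carrying posture implies (e.g. along −X for a phone upright in
    a trouser pocket).
    """

    name: str
    mag_mean: float                 # m/s², mean magnitude incl. gravity
    mag_std: float                  # m/s², magnitude std
    step_freq: float = 1.8          # Hz
    walk_speed: float = 1.4         # m/s
    orientation: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)
    gyro_level: float = 0.3         # rad/s per-axis RMS
    mag_field: tuple[float, float, float] = (30.0, 0.0, -40.0)  # µT, world
    mag_jitter: float = 1.0         # µT per-axis noise std
    acc_bias_std: float = 0.12      # m/s², per-trace constant offset, per axis

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ValueError(f"name must be one of {CONDITIONS}")
        if self.mag_mean <= 9.0:
            raise ValueError("mag_mean must exceed 9.0 m/s² (gravity included)")
        if self.mag_std < 0:
            raise ValueError("mag_std must be nonnegative")
        if not (0.5 < self.step_freq < 4.0):
            raise ValueError("step_freq must be in (0.5, 4) Hz")


@dataclass
class SubjectSpec:
    """Per-subject gait traits.

    The trait multipliers apply only under distraction (look/text):
    ``distraction_speed_drop`` is the extra fractional slow-down,
    ``var_distraction_mult`` scales magnitude variability, and
    ``gyro_distraction_mult`` / ``mag_distraction_mult`` scale gyroscope
    activity and magnetometer jitter (introverts hold the phone steadier).
    """

    subject_id: str = "S00"
    trait_ei: str = "E"
    speed_scale: float = 1.0
    variability_scale: float = 1.0
    distraction_speed_drop: float = 0.0
    mag_offset: float = 0.0             # m/s² baseline magnitude shift
    #: m/s² shift of the look/text magnitude mean only — how strongly this
    #: subject's acceleration drops under distraction varies across people
    distraction_mag_offset: float = 0.0
    step_freq_offset: float = 0.0  # Hz
    gyro_scale: float = 1.0
    var_distraction_mult: float = 1.0
    gyro_distraction_mult: float = 1.0
    mag_distraction_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.trait_ei not in ("E", "I"):
            raise ValueError("trait_ei must be 'E' or 'I'")
        if self.speed_scale <= 0 or self.variability_scale <= 0:
            raise ValueError("speed_scale and variability_scale must be positive")
        if not (0.0 <= self.distraction_speed_drop < 1.0):
            raise ValueError("distraction_speed_drop must be in [0, 1)")


@dataclass
class GroundTruth:
    """Reference trajectory in a local ENU frame (meters)."""

    time_s: np.ndarray      # (m,)
    positions: np.ndarray   # (m, 2)
    total_distance: float = field(init=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.time_s), 2):
            raise ValueError("positions must have shape (m, 2)")
        steps = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        self.total_distance = float(np.sum(steps))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def magnitude_mean_std(
    profile: ConditionProfile, duration_s: float = 90.0
) -> float:
    """Predicted std of the per-trace mean of the magnitude signal.

    The per-trace mean wanders because of the constant accelerometer bias
    (per-axis std ``acc_bias_std``, one component projecting onto the
    magnitude) and the time-average of the slow OU pace drift
    (Var = 2σ²τ/T·(1 − (τ/T)(1 − e^(−T/τ)))); oscillation and white noise
    average out.  Used to set Monte-Carlo tolerances when checking the
    generator's calibration.
    """
    tau = _SLOW_TAU_S
    t_ratio = tau / duration_s
    s_slow2 = profile.mag_std**2 * _VAR_SLOW / 0.78  # finite-sample factor
    wander_var = 2.0 * s_slow2 * t_ratio * (
        1.0 - t_ratio * (1.0 - math.exp(-duration_s / tau))
    )
    return math.sqrt(profile.acc_bias_std**2 + wander_var)


def default_profiles() -> dict[str, ConditionProfile]:
    """Packaged condition profiles calibrated to the study statistics.

    (mag_mean, mag_std): pocket (12.1, 0.60), look (10.0, 0.28),
    text (9.9, 0.27) m/s².  Cadence slows from 1.8 Hz in the pocket to
    1.6 Hz under distraction; gyroscope activity collapses when the phone
    is held in front of the body instead of swinging in the pocket.
    """
    pocket_orient = tuple(Rotation.from_euler("y", -90, degrees=True).as_quat())
    look_orient = tuple(Rotation.from_euler("x", 40, degrees=True).as_quat())
    text_orient = tuple(Rotation.from_euler("x", 25, degrees=True).as_quat())
    return {
        "pocket": ConditionProfile(
            name="pocket", mag_mean=12.1, mag_std=0.60, step_freq=1.8,
            walk_speed=1.4, orientation=pocket_orient, gyro_level=0.45,
            mag_jitter=1.5,
        ),
        "look": ConditionProfile(
            name="look", mag_mean=10.0, mag_std=0.28, step_freq=1.6,
            walk_speed=1.25, orientation=look_orient, gyro_level=0.12,
            mag_jitter=0.8,
        ),
        "text": ConditionProfile(
            name="text", mag_mean=9.9, mag_std=0.27, step_freq=1.6,
            walk_speed=1.2, orientation=text_orient, gyro_level=0.10,
            mag_jitter=0.8,
        ),
    }


def generate_trace(
    profile: ConditionProfile,
    subject: SubjectSpec | None = None,
    duration_s: float = 90.0,
    fs_hz: float = 100.0,
    seed: int = 0,
) -> tuple[SensorTrace, GroundTruth]:
    """Generate one seeded walking session for a subject under a condition.

    Returns the device-frame sensor trace (no GPS; attach one with
    :func:`generate_gps`) and the straight-line ground-truth trajectory at
    the subject's effective walking speed.  Identical arguments and seed
    give bit-identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_hz < 10:
        raise ValueError("fs_hz must be at least 10 Hz")
    subject = subject or SubjectSpec()
    distracted = profile.name in ("look", "text")

    mean = profile.mag_mean + subject.mag_offset
    if distracted:
        mean += subject.distraction_mag_offset
    sigma = profile.mag_std * subject.variability_scale
    if distracted:
        sigma *= subject.var_distraction_mult
    f = profile.step_freq + subject.step_freq_offset
    v_eff = profile.walk_speed * subject.speed_scale
    if distracted:
        v_eff *= 1.0 - subject.distraction_speed_drop

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    dt = 1.0 / fs_hz
    t = np.arange(n) * dt

    a1 = sigma * math.sqrt(2.0 * _VAR_FUNDAMENTAL)
    a2 = sigma * math.sqrt(2.0 * _VAR_HARMONIC)
    s_noise = sigma * math.sqrt(_VAR_NOISE)
    # correct the construction mean for the norm inflation caused by the
    # noise/bias components perpendicular to the signal vector
    mean_adj = mean - (s_noise**2 + profile.acc_bias_std**2) / mean
    ph = rng.uniform(0.0, 2.0 * np.pi, size=4)
    # slow pace drift: stationary OU process, within-trace nonstationarity.
    # The within-trace sample variance of an AR(1) underestimates its
    # stationary variance (the trace mean absorbs low-frequency power), so
    # the amplitude is scaled by the exact finite-sample variance factor to
    # keep the per-trace magnitude std on target.
    a_ou = math.exp(-dt / _SLOW_TAU_S)
    c_ou = math.sqrt(1.0 - a_ou * a_ou)
    d = np.arange(1, n)
    var_factor = 1.0 - (n + 2.0 * np.sum((n - d) * a_ou**d)) / n**2
    s_slow = sigma * math.sqrt(_VAR_SLOW / max(var_factor, 1e-6))
    w = rng.normal(0.0, 1.0, n)
    drive = c_ou * w
    drive[0] = w[0]  # stationary start
    slow = lfilter([1.0], [1.0, -a_ou], drive)
    m = (
        mean_adj
        + a1 * np.sin(2.0 * np.pi * f * t + ph[0])
        + a2 * np.sin(4.0 * np.pi * f * t + ph[1])
        + s_slow * slow
    )
    # small horizontal gait oscillations; step-frequency fore-aft, half-rate sway
    a_fore = 0.5 * sigma * np.sin(2.0 * np.pi * f * t + ph[2])
    a_sway = 0.3 * sigma * np.sin(np.pi * f * t + ph[3])
    vert = np.sqrt(np.maximum(m**2 - a_fore**2 - a_sway**2, 0.0))
    world = np.column_stack([a_fore, a_sway, vert])

    rot_w2d = Rotation.from_quat(np.asarray(profile.orientation, dtype=float))
    bias = rng.normal(0.0, profile.acc_bias_std, 3)
    acc = rot_w2d.apply(world) + bias + rng.normal(0.0, s_noise, (n, 3))

    g_level = profile.gyro_level * subject.gyro_scale
    if distracted:
        g_level *= subject.gyro_distraction_mult
    g_amp = g_level * math.sqrt(2.0 * 0.8)
    g_noise = g_level * math.sqrt(0.2)
    gph = rng.uniform(0.0, 2.0 * np.pi, size=3)
    gyro = np.column_stack([
        g_amp * np.sin(2.0 * np.pi * f * t + gph[0]),
        g_amp * np.sin(2.0 * np.pi * f * t + gph[1]),
        g_amp * np.sin(np.pi * f * t + gph[2]),
    ]) + rng.normal(0.0, g_noise, (n, 3))

    jitter = profile.mag_jitter
    if distracted:
        jitter *= subject.mag_distraction_mult
    mag = rot_w2d.apply(np.asarray(profile.mag_field, dtype=float)) + rng.normal(
        0.0, jitter, (n, 3)
    )

    meta = TraceMeta(
        subject_id=subject.subject_id,
        condition=profile.name,
        device="synthetic",
        trait_ei=subject.trait_ei,
        device_to_world=tuple(rot_w2d.inv().as_quat()),
    )
    trace = SensorTrace(
        time_ms=np.arange(n) * (1000.0 / fs_hz), acc=acc, gyro=gyro, mag=mag,
        meta=meta,
    )

    tt = np.arange(n + 1) * dt
    positions = np.column_stack([v_eff * tt, np.zeros(n + 1)])
    truth = GroundTruth(time_s=tt, positions=positions)
    return trace, truth


def generate_gps(
    truth: GroundTruth,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    rate_hz: float = 1.0,
    noise_std_m: float = 3.0,
    seed: int = 0,
    corr_time_s: float = 60.0,
) -> GpsTrack:
    """Sample noisy GPS fixes along a ground-truth trajectory.

    Fixes at ``1/rate_hz`` intervals from t = 0 through the end of the
    walk; each true position is perturbed by isotropic Gaussian noise of
    per-axis std ``noise_std_m`` and converted to (lat, lon) about
    ``origin`` by the inverse equirectangular projection.

    Receiver error is strongly autocorrelated over time (atmospheric and
    multipath biases drift slowly while consecutive fixes stay mutually
    consistent), so the noise is a stationary first-order Gauss–Markov
    process with correlation time ``corr_time_s``; the marginal per-axis
    distribution remains N(0, noise_std_m²) exactly.  ``corr_time_s = 0``
    gives independent (white) noise per fix.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if noise_std_m < 0:
        raise ValueError("noise_std_m must be nonnegative")
    if corr_time_s < 0:
        raise ValueError("corr_time_s must be nonnegative")
    rng = np.random.default_rng(seed)
    n_fix = int(np.floor(truth.duration_s * rate_hz + 1e-9)) + 1
    times = truth.time_s[0] + np.arange(n_fix) / rate_hz
    x = np.interp(times, truth.time_s, truth.positions[:, 0])
    y = np.interp(times, truth.time_s, truth.positions[:, 1])
    white = rng.normal(0.0, 1.0, (n_fix, 2))
    if corr_time_s > 0:
        rho = math.exp(-1.0 / (rate_hz * corr_time_s))
        e = np.empty_like(white)
        e[0] = white[0]
        c = math.sqrt(1.0 - rho * rho)
        for k in range(1, n_fix):
            e[k] = rho * e[k - 1] + c * white[k]
    else:
        e = white
    xy = np.column_stack([x, y]) + noise_std_m * e
    lat, lon = local_to_latlon(xy, origin)
    return GpsTrack(time_ms=times * 1000.0, lat=lat, lon=lon)


@dataclass
class CohortConfig:
    """Hyper-distributions for drawing subjects.

    ``trait_modulation`` switches the systematic E/I differences on or off;
    when off, every subject receives extravert-like (near-neutral)
    distraction multipliers, so trait labels carry no signal.
    """

    speed_scale_sd: float = 0.08
    variability_scale_sd: float = 0.25   # lognormal sigma
    mag_offset_sd: float = 0.35          # m/s²
    distraction_mag_offset_sd: float = 1.0  # m/s², clipped at 2 sd
    step_freq_sd: float = 0.08           # Hz
    gyro_scale_sd: float = 0.15          # lognormal sigma
    trait_modulation: bool = True
    # introvert distraction response
    i_speed_drop: tuple[float, float] = (0.15, 0.30)   # uniform range
    i_gyro_mult: tuple[float, float] = (0.65, 0.05)    # normal (mean, sd)
    i_mag_mult: tuple[float, float] = (0.70, 0.05)
    i_var_mult: tuple[float, float] = (0.85, 0.04)
    # extravert distraction response
    e_speed_drop: tuple[float, float] = (0.03, 0.10)
    e_gyro_mult: tuple[float, float] = (1.00, 0.05)
    e_mag_mult: tuple[float, float] = (1.00, 0.05)
    e_var_mult: tuple[float, float] = (1.00, 0.04)


def draw_subject(
    subject_id: str,
    trait_ei: str,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> SubjectSpec:
    """Draw one subject's gait traits from the cohort hyper-distributions."""
    cfg = config or CohortConfig()
    introvert = trait_ei == "I" and cfg.trait_modulation
    drop_lo, drop_hi = cfg.i_speed_drop if introvert else cfg.e_speed_drop
    gyro_m = cfg.i_gyro_mult if introvert else cfg.e_gyro_mult
    mag_m = cfg.i_mag_mult if introvert else cfg.e_mag_mult
    var_m = cfg.i_var_mult if introvert else cfg.e_var_mult
    return SubjectSpec(
        subject_id=subject_id,
        trait_ei=trait_ei,
        speed_scale=float(np.exp(rng.normal(0.0, cfg.speed_scale_sd))),
        variability_scale=float(np.exp(rng.normal(0.0, cfg.variability_scale_sd))),
        distraction_speed_drop=float(rng.uniform(drop_lo, drop_hi)),
        mag_offset=float(rng.normal(0.0, cfg.mag_offset_sd)),
        distraction_mag_offset=float(np.clip(
            rng.normal(0.0, cfg.distraction_mag_offset_sd),
            -2.0 * cfg.distraction_mag_offset_sd,
            2.0 * cfg.distraction_mag_offset_sd,
        )),
        step_freq_offset=float(rng.normal(0.0, cfg.step_freq_sd)),
        gyro_scale=float(np.exp(rng.normal(0.0, cfg.gyro_scale_sd))),
        var_distraction_mult=max(float(rng.normal(*var_m)), 0.05),
        gyro_distraction_mult=max(float(rng.normal(*gyro_m)), 0.05),
        mag_distraction_mult=max(float(rng.normal(*mag_m)), 0.05),
    )


def generate_cohort(
    n_subjects: int = 21,
    conditions: tuple[str, ...] = CONDITIONS,
    reps: int = 5,
    seed: int = 0,
    duration_s: float = 90.0,
    fs_hz: float = 100.0,
    profiles: dict[str, ConditionProfile] | None = None,
    config: CohortConfig | None = None,
    with_gps: bool = False,
    gps_rate_hz: float = 1.0,
    gps_noise_std_m: float = 3.0,
    gps_corr_time_s: float = 60.0,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
) -> list[tuple[SensorTrace, GroundTruth]]:
    """Generate a full cohort: per subject, per condition, ``reps`` traces.

    E/I traits are assigned alternately (S01 = E, S02 = I, ...); subject
    specs are drawn from the cohort hyper-distributions.  Deterministic
    under ``seed``.
    """
    if n_subjects < 1 or reps < 1:
        raise ValueError("n_subjects and reps must be >= 1")
    profiles = profiles or default_profiles()
    unknown = [c for c in conditions if c not in profiles]
    if unknown:
        raise ValueError(f"no profile for condition(s) {unknown}")
    rng = np.random.default_rng(seed)
    subjects = [
        draw_subject(f"S{i + 1:02d}", "E" if i % 2 == 0 else "I", rng, config)
        for i in range(n_subjects)
    ]
    out: list[tuple[SensorTrace, GroundTruth]] = []
    for subj in subjects:
        for cond in conditions:
            for rep in range(1, reps + 1):
                s_trace = int(rng.integers(2**31))
                s_gps = int(rng.integers(2**31))
                trace, truth = generate_trace(
                    profiles[cond], subj, duration_s, fs_hz, seed=s_trace
                )
                trace.meta = replace(trace.meta, rep=rep)
                if with_gps:
                    trace.gps = generate_gps(
                        truth, origin, gps_rate_hz, gps_noise_std_m,
                        seed=s_gps, corr_time_s=gps_corr_time_s,
                    )
                out.append((trace, truth))
    return out
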