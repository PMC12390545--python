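"""Kalman-fusion distance estimation from accelerometer and GPS.

The walker is modeled with a planar constant-velocity state
``X = [x, vx, y, vy]`` (meters, m/s).  Accelerometer samples, rotated into
the world frame and with gravity removed, drive the prediction step as a
control input; GPS position fixes (converted to local meters by an
equirectangular projection) correct the accumulated drift in the update
step.  The filter is linear: the transition and control matrices are

    A = [[1, dt, 0, 0],          B = [[dt²/2, 0],
         [0, 1,  0, 0],               [dt,    0],
         [0, 0,  1, dt],              [0, dt²/2],
         [0, 0,  0, 1]]               [0,    dt]]

with measurement matrix H picking the two position components.  Default
noise settings: process noise Q = 0.1·I₄ (soft, continuous human motion),
measurement noise R = 5.01·I₂ m² (typical open-sky GPS error of a few
meters per axis), initial covariance P₀ = 300·I₄ for fast initial
correction, and a propagation step of 0.01 s matching the interpolated
sensor cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .sensor_io import GpsFix, GpsTrack, InsufficientDataError, SensorTrace

__all__ = [
    "EARTH_RADIUS_M",
    "GRAVITY_M_S2",
    "FusionConfig",
    "FusionState",
    "FusionResult",
    "make_matrices",
    "predict",
    "update",
    "run_fusion",
    "evaluate_distance",
    "latlon_to_local",
    "local_to_latlon",
]

EARTH_RADIUS_M = 6_371_000.0
GRAVITY_M_S2 = 9.80665

_H = np.array([[1.0, 0.0, 0.0, 0.0],
               [0.0, 0.0, 1.0, 0.0]])


def _check_spd(name: str, m: np.ndarray, size: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (size, size):
        raise ValueError(f"{name} must be {size}x{size}")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(m)) < -1e-9:
        raise ValueError(f"{name} must be positive semi-definite")
    return m


@dataclass
class FusionConfig:
    """Noise settings and propagation step for the position filter."""

    dt: float = 0.01
    Q: np.ndarray = field(default_factory=lambda: 0.1 * np.eye(4))
    R: np.ndarray = field(default_factory=lambda: 5.01 * np.eye(2))
    P0: np.ndarray = field(default_factory=lambda: 300.0 * np.eye(4))
    gravity: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, GRAVITY_M_S2])
    )
    #: seed the initial position/velocity from the first two GPS fixes
    #: (the large P0 lets the filter refine them quickly either way)
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.Q = _check_spd("Q", self.Q, 4)
        self.R = _check_spd("R", self.R, 2)
        self.P0 = _check_spd("P0", self.P0, 4)
        self.gravity = np.asarray(self.gravity, dtype=float)


@dataclass
class FusionState:
    """Filter state: X = [x, vx, y, vy], covariance P, time t (s)."""

    X: np.ndarray = field(default_factory=lambda: np.zeros(4))
    P: np.ndarray = field(default_factory=lambda: 300.0 * np.eye(4))
    t: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).reshape(4)
        self.P = _check_spd("P", self.P, 4)

    @property
    def position(self) -> np.ndarray:
        return self.X[[0, 2]]

    @property
    def velocity(self) -> np.ndarray:
        return self.X[[1, 3]]


def make_matrices(dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Constant-velocity transition A and acceleration control matrix B."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = np.array([
        [1.0, dt, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, dt],
        [0.0, 0.0, 0.0, 1.0],
    ])
    B = np.array([
        [0.5 * dt * dt, 0.0],
        [dt, 0.0],
        [0.0, 0.5 * dt * dt],
        [0.0, dt],
    ])
    return A, B


def predict(state: FusionState, accel_xy, config: FusionConfig) -> FusionState:
    """Propagate one step with planar acceleration as control input."""
    u = np.asarray(accel_xy, dtype=float).reshape(2)
    if not np.all(np.isfinite(u)):
        raise ValueError("acceleration input must be finite")
    A, B = make_matrices(config.dt)
    X = A @ state.X + B @ u
    P = A @ state.P @ A.T + config.Q
    out = FusionState.__new__(FusionState)
    out.X, out.P, out.t = X, P, state.t + config.dt
    return out


def update(state: FusionState, gps_xy, config: FusionConfig) -> FusionState:
    """Kalman measurement update with a planar GPS position fix."""
    z = np.asarray(gps_xy, dtype=float).reshape(2)
    if not np.all(np.isfinite(z)):
        raise ValueError("GPS measurement must be finite")
    P = state.P
    S = _H @ P @ _H.T + config.R
    K = P @ _H.T @ np.linalg.inv(S)
    X = state.X + K @ (z - _H @ state.X)
    P = (np.eye(4) - K @ _H) @ P
    P = 0.5 * (P + P.T)
    out = FusionState.__new__(FusionState)
    out.X, out.P, out.t = X, P, state.t
    return out


def kalman_gain(state: FusionState, config: FusionConfig) -> np.ndarray:
    """The 4x2 gain the next :func:`update` would use."""
    S = _H @ state.P @ _H.T + config.R
    return state.P @ _H.T @ np.linalg.inv(S)


def latlon_to_local(fix: GpsFix | tuple[float, float], origin: tuple[float, float]) -> np.ndarray:
    """Project (lat, lon) degrees to local ENU meters about ``origin``.

    Equirectangular: x = R·Δlon·cos(lat₀), y = R·Δlat (radians).  Valid for
    fixes within 1° of the origin; gait paths are a few hundred meters.
    """
    if isinstance(fix, GpsFix):
        lat, lon = fix.lat, fix.lon
    else:
        lat, lon = fix
    lat0, lon0 = origin
    if abs(lat - lat0) >= 1.0 or abs(lon - lon0) >= 1.0:
        raise ValueError("fix more than 1 degree from origin")
    x = EARTH_RADIUS_M * np.radians(lon - lon0) * np.cos(np.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return np.array([x, y])


def local_to_latlon(xy, origin: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`latlon_to_local` (vectorized over rows of ``xy``)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    lat0, lon0 = origin
    lat = lat0 + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(xy[:, 0] / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    return lat, lon


@dataclass
class FusionResult:
    """Estimated trajectory (world meters) and accumulated walked distance.

    The walked distance accumulates the motion-model displacement of each
    prediction step; a GPS measurement update corrects the state (and hence
    where subsequent steps start from) but its correction jump is not
    itself walked distance.
    """

    time_s: np.ndarray               # (n,)
    trajectory: np.ndarray           # (n, 2), post-update positions
    cumulative_distance: np.ndarray  # (n,)
    distance_m: float
    final_state: FusionState


def _as_rotation(spec) -> Rotation:
    if spec is None:
        return Rotation.identity()
    if isinstance(spec, Rotation):
        return spec
    return Rotation.from_quat(np.asarray(spec, dtype=float))


def run_fusion(
    trace: SensorTrace,
    accel_to_world=None,
    config: FusionConfig | None = None,
    origin: tuple[float, float] | None = None,
) -> FusionResult:
    """Run the filter over a uniformly resampled trace.

    ``accel_to_world`` is a device→world rotation (scipy Rotation or
    quaternion); if omitted, the rotation stored in ``trace.meta`` is used,
    falling back to identity.  GPS fixes are applied at the propagation step
    nearest each fix timestamp (ties round down); ``origin`` defaults to the
    first fix.
    """
    config = config or FusionConfig()
    if len(trace) < 2:
        raise InsufficientDataError("fusion needs at least 2 samples")
    grid_dt = trace.grid_dt_s()
    if abs(grid_dt - config.dt) > 1e-9 * max(config.dt, 1.0):
        raise ValueError(
            f"trace grid step {grid_dt} s does not match config.dt {config.dt} s; "
            "resample the trace first"
        )
    rot = _as_rotation(
        accel_to_world if accel_to_world is not None else trace.meta.device_to_world
    )
    acc_world = rot.apply(trace.acc) - config.gravity
    acc_xy = acc_world[:, :2]

    gps_at: dict[int, np.ndarray] = {}
    if len(trace.gps):
        if origin is None:
            origin = (float(trace.gps.lat[0]), float(trace.gps.lon[0]))
        t0 = trace.time_ms[0]
        for fix in trace.gps:
            # nearest grid step; exact half-way ties round down
            k = int(np.ceil((fix.time_ms - t0) / (config.dt * 1000.0) - 0.5))
            k = min(max(k, 0), len(trace) - 1)
            gps_at[k] = latlon_to_local(fix, origin)

    A, B = make_matrices(config.dt)
    X = np.zeros(4)
    if config.warm_start and len(trace.gps) >= 2:
        p0 = latlon_to_local(trace.gps[0], origin)
        p1 = latlon_to_local(trace.gps[1], origin)
        dt_fix = (trace.gps.time_ms[1] - trace.gps.time_ms[0]) / 1000.0
        if dt_fix > 0:
            v0 = (p1 - p0) / dt_fix
            X = np.array([p0[0], v0[0], p0[1], v0[1]])
    P = config.P0.copy()
    H = _H
    R = config.R
    Q = config.Q
    traj = np.empty((len(trace), 2))
    cum = np.empty(len(trace))
    traj[0] = X[[0, 2]]
    cum[0] = 0.0
    if 0 in gps_at:
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        X = X + K @ (gps_at[0] - H @ X)
        P = (np.eye(4) - K @ H) @ P
        P = 0.5 * (P + P.T)
        traj[0] = X[[0, 2]]
    dist = 0.0
    for k in range(1, len(trace)):
        x_prev, y_prev = X[0], X[2]
        X = A @ X + B @ acc_xy[k - 1]
        P = A @ P @ A.T + Q
        dist += float(np.hypot(X[0] - x_prev, X[2] - y_prev))
        z = gps_at.get(k)
        if z is not None:
            S = H @ P @ H.T + R
            K = P @ H.T @ np.linalg.inv(S)
            X = X + K @ (z - H @ X)
            P = (np.eye(4) - K @ H) @ P
            P = 0.5 * (P + P.T)
        traj[k] = X[[0, 2]]
        cum[k] = dist

    final = FusionState.__new__(FusionState)
    final.X, final.P, final.t = X, P, float(trace.time_s[-1] - trace.time_s[0])
    return FusionResult(
        time_s=trace.time_s - trace.time_s[0],
        trajectory=traj,
        cumulative_distance=cum,
        distance_m=dist,
        final_state=final,
    )


def evaluate_distance(predicted, truth) -> tuple[float, float, float]:
    """MAE, RMSE and total-distance error rate against ground truth.

    ``predicted`` is a :class:`FusionResult` or a ``(time_s, cumdist)``
    pair; ``truth`` is a ``GroundTruth`` (from the synthetic generator) or a
    ``(time_s, cumdist)`` pair.  Errors are computed on the cumulative
    walked-distance series, truth interpolated to the predicted time base;
    the error rate is ``|pred_total − true_total| / true_total``.
    """
    if isinstance(predicted, FusionResult):
        t_pred = predicted.time_s
        d_pred = predicted.cumulative_distance
    else:
        t_pred, d_pred = (np.asarray(a, dtype=float) for a in predicted)
    if hasattr(truth, "time_s") and hasattr(truth, "positions"):
        t_true = truth.time_s
        steps = np.linalg.norm(np.diff(truth.positions, axis=0), axis=1)
        d_true = np.concatenate([[0.0], np.cumsum(steps)])
    else:
        t_true, d_true = (np.asarray(a, dtype=float) for a in truth)
    if len(t_pred) == 0 or len(t_true) == 0:
        raise InsufficientDataError("empty input to evaluate_distance")
    d_true_on_pred = np.interp(t_pred, t_true, d_true)
    err = d_pred - d_true_on_pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    total_true = float(d_true[-1])
    if total_true == 0:
        raise InsufficientDataError("ground-truth distance is zero")
    error_rate = abs(float(d_pred[-1]) - total_true) / total_true
    return mae, rmse, error_rate
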