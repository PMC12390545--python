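"""Reading, writing, resampling and denoising smartphone sensor traces.

A trace is a 9-channel IMU stream (3-axis accelerometer in m/s², 3-axis
gyroscope in rad/s, 3-axis magnetometer in µT) sampled at irregular
millisecond timestamps, optionally accompanied by sparse GPS fixes
(latitude/longitude in degrees).  The CSV schema is::

    Time(ms),AccX,AccY,AccZ,GyroX,GyroY,GyroZ,MagX,MagY,MagZ[,Lat,Lon]

Timestamps are milliseconds on disk and are kept in milliseconds in
:class:`SensorTrace`; seconds are derived where needed.  GPS fixes are
event-based and are never interpolated — only the IMU channels are
resampled onto a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMU_COLUMNS",
    "GPS_COLUMNS",
    "ImuSample",
    "GpsFix",
    "GpsTrack",
    "TraceMeta",
    "SensorTrace",
    "SchemaError",
    "OrderingError",
    "InsufficientDataError",
    "read_trace_csv",
    "write_trace_csv",
    "resample",
    "moving_average",
    "smooth_trace",
]

IMU_COLUMNS = (
    "Time(ms)",
    "AccX", "AccY", "AccZ",
    "GyroX", "GyroY", "GyroZ",
    "MagX", "MagY", "MagZ",
)
GPS_COLUMNS = ("Lat", "Lon")

CONDITIONS = ("pocket", "look", "text")


class SchemaError(ValueError):
    """The CSV header does not contain the mandatory columns."""


class OrderingError(ValueError):
    """Timestamps are not monotone."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested operation."""


@dataclass(frozen=True)
class ImuSample:
    """One row of the 9-channel IMU stream."""

    time_ms: float
    acc: np.ndarray   # (3,) m/s²
    gyro: np.ndarray  # (3,) rad/s
    mag: np.ndarray   # (3,) µT


@dataclass(frozen=True)
class GpsFix:
    """A single GPS position fix."""

    time_ms: float
    lat: float  # degrees
    lon: float  # degrees

    def __post_init__(self) -> None:
        if not (abs(self.lat) <= 90.0 and abs(self.lon) <= 180.0):
            raise ValueError(f"invalid GPS fix lat={self.lat}, lon={self.lon}")


class GpsTrack:
    """Ordered sequence of GPS fixes, stored columnar."""

    def __init__(self, time_ms: np.ndarray, lat: np.ndarray, lon: np.ndarray):
        self.time_ms = np.asarray(time_ms, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        if not (self.time_ms.shape == self.lat.shape == self.lon.shape):
            raise ValueError("GPS arrays must have equal length")
        if np.any(np.diff(self.time_ms) < 0):
            raise OrderingError("GPS fix timestamps must be nondecreasing")
        if np.any(np.abs(self.lat) > 90.0) or np.any(np.abs(self.lon) > 180.0):
            raise ValueError("GPS fixes out of range")

    def __len__(self) -> int:
        return len(self.time_ms)

    def __getitem__(self, i: int) -> GpsFix:
        return GpsFix(float(self.time_ms[i]), float(self.lat[i]), float(self.lon[i]))

    def __iter__(self) -> Iterator[GpsFix]:
        return (self[i] for i in range(len(self)))

    @classmethod
    def empty(cls) -> "GpsTrack":
        z = np.empty(0)
        return cls(z, z, z)


@dataclass
class TraceMeta:
    """Session metadata attached to a trace.

    ``condition`` is one of pocket (phone in pocket, normal gait), look
    (screen viewing while walking) or text (messaging while walking), or
    empty when unknown.  ``device_to_world`` is an optional quaternion
    (x, y, z, w) giving the static rotation from the device frame to the
    world (ENU) frame, emitted by the synthetic generator and consumed by
    the fusion stage.
    """

    subject_id: str = ""
    condition: str = ""
    device: str = ""
    rep: int = 0
    trait_ei: str = ""
    device_to_world: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class SensorTrace:
    """A timestamped 9-channel IMU stream plus optional GPS fixes."""

    time_ms: np.ndarray            # (n,)
    acc: np.ndarray                # (n, 3) m/s²
    gyro: np.ndarray               # (n, 3) rad/s
    mag: np.ndarray                # (n, 3) µT
    gps: GpsTrack = field(default_factory=GpsTrack.empty)
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        for name in ("acc", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.time_ms), 3):
                raise ValueError(f"{name} must have shape (n, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if len(self.time_ms) and self.time_ms[0] < 0:
            raise ValueError("timestamps must be nonnegative")
        bad = np.nonzero(np.diff(self.time_ms) <= 0)[0]
        if bad.size:
            raise OrderingError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def time_s(self) -> np.ndarray:
        return self.time_ms / 1000.0

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float((self.time_ms[-1] - self.time_ms[0]) / 1000.0)

    @property
    def samples(self) -> Iterator[ImuSample]:
        for i in range(len(self)):
            yield ImuSample(
                float(self.time_ms[i]), self.acc[i], self.gyro[i], self.mag[i]
            )

    def grid_dt_s(self, rtol: float = 1e-6) -> float:
        """Return the uniform grid step in seconds.

        Raises :class:`ValueError` if the timestamps are not (approximately)
        uniformly spaced.
        """
        if len(self) < 2:
            raise InsufficientDataError("need >= 2 samples to define a grid")
        steps = np.diff(self.time_ms)
        dt = float(np.median(steps))
        if np.max(np.abs(steps - dt)) > rtol * max(dt, 1.0):
            raise ValueError("trace is not on a uniform grid")
        return dt / 1000.0


def read_trace_csv(path: str | Path, meta: TraceMeta | None = None) -> SensorTrace:
    """Read a sensor trace from a CSV file in the Table-schema dialect.

    Rows with unparseable numeric fields in the mandatory columns are
    dropped.  Optional ``Lat``/``Lon`` columns supply GPS fixes on the rows
    where both are present.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    num = df[list(IMU_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    valid = num.notna().all(axis=1)
    num = num[valid]

    t = num["Time(ms)"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # report the 1-based data row index of the offending row
        row = int(num.index[bad[0] + 1]) + 1
        raise OrderingError(f"{path}: non-monotone timestamp at data row {row}")

    gps = GpsTrack.empty()
    if all(c in df.columns for c in GPS_COLUMNS):
        g = df.loc[valid, list(GPS_COLUMNS)].apply(pd.to_numeric, errors="coerce")
        has_fix = g.notna().all(axis=1)
        if has_fix.any():
            gps = GpsTrack(
                t[has_fix.to_numpy()],
                g.loc[has_fix, "Lat"].to_numpy(dtype=float),
                g.loc[has_fix, "Lon"].to_numpy(dtype=float),
            )

    return SensorTrace(
        time_ms=t,
        acc=num[["AccX", "AccY", "AccZ"]].to_numpy(dtype=float),
        gyro=num[["GyroX", "GyroY", "GyroZ"]].to_numpy(dtype=float),
        mag=num[["MagX", "MagY", "MagZ"]].to_numpy(dtype=float),
        gps=gps,
        meta=meta if meta is not None else TraceMeta(),
    )


def write_trace_csv(trace: SensorTrace, path: str | Path) -> None:
    """Write a trace in the CSV dialect read by :func:`read_trace_csv`.

    Values are printed with Python's shortest round-tripping ``repr`` so a
    read-back trace is bit-identical where representable.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "Time(ms)": trace.time_ms,
        "AccX": trace.acc[:, 0], "AccY": trace.acc[:, 1], "AccZ": trace.acc[:, 2],
        "GyroX": trace.gyro[:, 0], "GyroY": trace.gyro[:, 1], "GyroZ": trace.gyro[:, 2],
        "MagX": trace.mag[:, 0], "MagY": trace.mag[:, 1], "MagZ": trace.mag[:, 2],
    }
    n = len(trace)
    lines = [",".join(list(cols) + (list(GPS_COLUMNS) if len(trace.gps) else []))]
    if len(trace.gps):
        fix_at = {float(t): i for i, t in enumerate(trace.gps.time_ms)}
    else:
        fix_at = {}
    for i in range(n):
        row = [repr(float(cols[c][i])) for c in cols]
        if fix_at:
            j = fix_at.get(float(trace.time_ms[i]))
            if j is None:
                row += ["", ""]
            else:
                row += [repr(float(trace.gps.lat[j])), repr(float(trace.gps.lon[j]))]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def resample(trace: SensorTrace, dt_s: float) -> SensorTrace:
    """Resample the IMU channels onto a uniform grid of step ``dt_s``.

    The output grid is the arithmetic sequence ``first + k * dt_s * 1000`` ms
    spanning ``[first, last]``; each channel is linearly interpolated between
    the bracketing input samples.  GPS fixes pass through untouched.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if len(trace) < 2:
        raise InsufficientDataError("resample needs at least 2 samples")
    step_ms = dt_s * 1000.0
    span = trace.time_ms[-1] - trace.time_ms[0]
    n = int(np.floor(span / step_ms + 1e-9)) + 1
    grid = trace.time_ms[0] + np.arange(n) * step_ms

    def interp(channel: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [np.interp(grid, trace.time_ms, channel[:, k]) for k in range(3)]
        )

    return SensorTrace(
        time_ms=grid,
        acc=interp(trace.acc),
        gyro=interp(trace.gyro),
        mag=interp(trace.mag),
        gps=trace.gps,
        meta=replace(trace.meta),
    )


def moving_average(signal: Sequence[float] | np.ndarray, window_n: int) -> np.ndarray:
    """Centered moving average with a truncated window at the edges.

    ``window_n`` must be odd so the window is symmetric; near the edges the
    mean is taken over the neighbors that exist (no padding), so the output
    has the same length as the input and never leaves ``[min, max]`` of the
    input.
    """
    if window_n < 1 or window_n % 2 == 0:
        raise ValueError("window_n must be an odd positive integer")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("signal must be a nonempty 1-D series")
    if window_n == 1:
        return x.copy()
    n = len(x)
    half = window_n // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    starts = np.maximum(idx - half, 0)
    ends = np.minimum(idx + half + 1, n)
    return (csum[ends] - csum[starts]) / (ends - starts)


def smooth_trace(trace: SensorTrace, window_n: int = 5) -> SensorTrace:
    """Apply the moving-average filter to all nine IMU channels."""
    def smooth(channel: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [moving_average(channel[:, k], window_n) for k in range(3)]
        )

    return SensorTrace(
        time_ms=trace.time_ms.copy(),
        acc=smooth(trace.acc),
        gyro=smooth(trace.gyro),
        mag=smooth(trace.mag),
        gps=trace.gps,
        meta=replace(trace.meta),
    )
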