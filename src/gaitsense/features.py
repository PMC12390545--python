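"""Windowed gait features from the acceleration-magnitude signal.

The core signal is the Euclidean norm of the 3-axis accelerometer,
``sqrt(AccX² + AccY² + AccZ²)`` (gravity included).  Each trace is cut
into consecutive non-overlapping 1-second windows and summarized as:

* ``avg_speed`` / ``max_speed`` — mean / max of the magnitude signal.
  The names follow the field's convention for these statistics even
  though the units are m/s²: they are derived from the magnitude signal,
  not an integrated velocity.
* ``std_speed`` — population std of the first differences of the
  magnitude ("speed changes"), the gait-variability statistic that
  separates pocket carrying from on-screen distraction.
* ``mean_jerk`` / ``max_jerk`` — mean / max of |Δmagnitude| / dt (m/s³).
* ``gyro_mean/std`` and ``mag_mean/std`` — mean / std of the gyroscope and
  magnetometer vector norms (orientation-invariant).

The ``accel_only`` feature subset is {avg_speed, max_speed, std_speed};
``multi_sensor`` adds the jerk, gyroscope and magnetometer columns (nine
features total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor_io import InsufficientDataError, SensorTrace

__all__ = [
    "ACCEL_FEATURES",
    "MULTI_SENSOR_FEATURES",
    "DEFAULT_LABEL_MAP",
    "WindowFeatures",
    "FeatureTable",
    "magnitude",
    "windowize",
    "extract_features",
    "build_feature_table",
    "with_trait_labels",
]

ACCEL_FEATURES = ("avg_speed", "max_speed", "std_speed")
MULTI_SENSOR_FEATURES = ACCEL_FEATURES + (
    "mean_jerk", "max_jerk", "gyro_mean", "gyro_std", "mag_mean", "mag_std",
)

#: look/text are distracted walking ("abnormal"); pocket is the baseline
DEFAULT_LABEL_MAP = {"pocket": "normal", "look": "abnormal", "text": "abnormal"}

TABLE_COLUMNS = (
    "subject_id", "condition", "rep", "window_index",
    *MULTI_SENSOR_FEATURES, "label",
)


@dataclass(frozen=True)
class WindowFeatures:
    """The per-window feature vector fed to classifiers."""

    avg_speed: float
    max_speed: float
    std_speed: float
    mean_jerk: float
    max_jerk: float
    gyro_mean: float
    gyro_std: float
    mag_mean: float
    mag_std: float
    label: str = ""
    subject_id: str = ""
    window_index: int = 0


def magnitude(acc) -> np.ndarray | float:
    """Euclidean norm of the 3-axis acceleration (gravity included)."""
    arr = np.asarray(acc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("acceleration must be finite")
    if arr.ndim == 1:
        return float(np.linalg.norm(arr))
    return np.linalg.norm(arr, axis=1)


def windowize(trace: SensorTrace, window_s: float = 1.0) -> list[slice]:
    """Cut a uniform-grid trace into consecutive non-overlapping windows.

    Window ``i`` covers ``[i·window_s, (i+1)·window_s)`` (half-open); a
    trailing partial window is dropped.  Returns index slices into the
    trace arrays.
    """
    dt = trace.grid_dt_s()
    per = window_s / dt
    n_per = int(round(per))
    if abs(per - n_per) > 1e-6 or n_per < 1:
        raise ValueError("window_s must be a multiple of the grid step")
    n_win = len(trace) // n_per
    return [slice(i * n_per, (i + 1) * n_per) for i in range(n_win)]


def extract_features(
    mag_signal: np.ndarray,
    grid_dt: float,
    gyro_norm: np.ndarray | None = None,
    mag_norm: np.ndarray | None = None,
    label: str = "",
    subject_id: str = "",
    window_index: int = 0,
) -> WindowFeatures:
    """Summarize one window of the magnitude signal (plus gyro/mag norms).

    ``std_speed`` is the population (n-normalized) std of the consecutive
    differences of the magnitude; the jerk series is |Δmagnitude| / dt.
    """
    m = np.asarray(mag_signal, dtype=float)
    if len(m) < 2:
        raise InsufficientDataError(
            "a window needs >= 2 samples to form differences"
        )
    diffs = np.diff(m)
    jerk = np.abs(diffs) / grid_dt
    gyro_norm = np.zeros_like(m) if gyro_norm is None else np.asarray(gyro_norm)
    mag_norm = np.zeros_like(m) if mag_norm is None else np.asarray(mag_norm)
    return WindowFeatures(
        avg_speed=float(np.mean(m)),
        max_speed=float(np.max(m)),
        std_speed=float(np.std(diffs)),
        mean_jerk=float(np.mean(jerk)),
        max_jerk=float(np.max(jerk)),
        gyro_mean=float(np.mean(gyro_norm)),
        gyro_std=float(np.std(gyro_norm)),
        mag_mean=float(np.mean(mag_norm)),
        mag_std=float(np.std(mag_norm)),
        label=label,
        subject_id=subject_id,
        window_index=window_index,
    )


def window_features(
    trace: SensorTrace, window_s: float = 1.0, label: str = ""
) -> list[WindowFeatures]:
    """All per-window feature vectors of one trace."""
    dt = trace.grid_dt_s()
    m = magnitude(trace.acc)
    g = np.linalg.norm(trace.gyro, axis=1)
    b = np.linalg.norm(trace.mag, axis=1)
    return [
        extract_features(
            m[w], dt, g[w], b[w],
            label=label,
            subject_id=trace.meta.subject_id,
            window_index=i,
        )
        for i, w in enumerate(windowize(trace, window_s))
    ]


@dataclass
class FeatureTable:
    """Window-level feature rows plus the active feature subset."""

    df: pd.DataFrame
    feature_subset: str = "accel_only"

    def __post_init__(self) -> None:
        if self.feature_subset not in ("accel_only", "multi_sensor"):
            raise ValueError("feature_subset must be accel_only or multi_sensor")
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing column(s) {missing}")

    @property
    def feature_columns(self) -> list[str]:
        if self.feature_subset == "accel_only":
            return list(ACCEL_FEATURES)
        return list(MULTI_SENSOR_FEATURES)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, feature_subset: str = "accel_only") -> "FeatureTable":
        return cls(pd.read_csv(path), feature_subset)


def build_feature_table(
    traces,
    subset: str = "accel_only",
    label_map: dict[str, str] | None = None,
    window_s: float = 1.0,
) -> FeatureTable:
    """One feature row per window per trace, labeled through ``label_map``.

    ``traces`` is an iterable of :class:`SensorTrace` (or (trace, truth)
    pairs as produced by the cohort generator).  Rows are ordered by
    (subject, condition, rep, window_index).
    """
    label_map = label_map if label_map is not None else dict(DEFAULT_LABEL_MAP)
    rows = []
    items = list(traces)
    if not items:
        raise ValueError("no traces given")
    for item in items:
        trace = item[0] if isinstance(item, tuple) else item
        cond = trace.meta.condition
        if cond not in label_map:
            raise KeyError(f"no label mapping for condition {cond!r}")
        for wf in window_features(trace, window_s, label=label_map[cond]):
            rows.append({
                "subject_id": trace.meta.subject_id,
                "condition": cond,
                "rep": trace.meta.rep,
                "window_index": wf.window_index,
                **{k: getattr(wf, k) for k in MULTI_SENSOR_FEATURES},
                "label": wf.label,
            })
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    df = df.sort_values(
        ["subject_id", "condition", "rep", "window_index"], kind="mergesort"
    ).reset_index(drop=True)
    return FeatureTable(df, subset)


def with_trait_labels(
    table: FeatureTable, trait_map: dict[str, str]
) -> FeatureTable:
    """Relabel a feature table with per-subject E/I traits.

    ``trait_map`` maps subject_id → 'E' | 'I'; the window rows themselves
    are unchanged.
    """
    missing = sorted(set(table.df["subject_id"]) - set(trait_map))
    if missing:
        raise KeyError(f"no trait for subject(s) {missing}")
    df = table.df.copy()
    df["label"] = df["subject_id"].map(trait_map)
    return FeatureTable(df, table.feature_subset)
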