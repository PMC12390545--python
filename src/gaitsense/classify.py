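"""Gait classification harness: six classifiers, three evaluation protocols.

Models (scikit-learn / xgboost): random forest (100 trees, unrestricted
depth), XGBoost (log-loss objective, seeded), decision tree (Gini,
unrestricted), k-nearest neighbors (k searched in 3–10, Euclidean, uniform
weights), RBF-kernel SVM (C searched in 0.1–100, gamma scaled) and
L2-regularized logistic regression (liblinear, C searched in 0.1–100).
Distance- and margin-based models are standardized in-pipeline.

Protocols:

* **personalized** — per subject, a stratified train/test split of that
  subject's own windows; metrics are reported per subject and aggregated
  as the unweighted mean over subjects.
* **loso** — leave-one-subject-out: each fold trains on every other
  subject's windows and tests on the held-out subject, measuring
  cross-subject generalization.
* **ei** — subject-grouped cross-validation on extraversion/introversion
  trait labels, run for the accelerometer-only and multi-sensor feature
  subsets to quantify what the extra channels buy.

AUC is computed by an explicit threshold sweep over the scores with
trapezoidal integration (ties collapsed), which makes it identical to the
normalized Mann–Whitney U statistic; the positive class is ``abnormal``
(distracted walking) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .features import FeatureTable, with_trait_labels

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "FittedModel",
    "EvalReport",
    "default_model_specs",
    "train_model",
    "compute_metrics",
    "roc_sweep",
    "evaluate_personalized",
    "evaluate_loso",
    "evaluate_ei",
    "compare_ei",
    "shuffle_labels_within_subject",
]

MODEL_NAMES = (
    "random_forest",
    "xgboost",
    "decision_tree",
    "knn",
    "svm",
    "logistic_regression",
)

#: tuned-parameter grid for XGBoost (named tuned parameters; desk-scale grid)
XGB_SEARCH_GRID = {
    "n_estimators": [100, 200],
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.3],
    "subsample": [0.8, 1.0],
    "colsample_bytree": [0.8, 1.0],
}


@dataclass
class ModelSpec:
    """A classifier choice with its hyperparameters and optional search grid."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    param_grid: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        k = self.hyperparams.get("n_neighbors")
        if self.name == "knn" and k is not None and not (3 <= k <= 10):
            raise ValueError("knn n_neighbors must be in 3..10")
        c = self.hyperparams.get("C")
        if self.name in ("svm", "logistic_regression") and c is not None:
            if not (0.1 <= c <= 100):
                raise ValueError("C must be in [0.1, 100]")


def default_model_specs(seed: int = 42, search: bool = False) -> dict[str, ModelSpec]:
    """The six study classifiers with their documented settings.

    With ``search=True``, models whose settings are specified as a range
    (knn k, SVM/logistic C, the XGBoost grid) carry a grid searched by
    stratified 3-fold CV on the training rows.
    """
    return {
        "random_forest": ModelSpec(
            "random_forest", {"n_estimators": 100, "max_depth": None}, seed=seed
        ),
        "xgboost": ModelSpec(
            "xgboost",
            {"n_estimators": 100, "eval_metric": "logloss"},
            param_grid=dict(XGB_SEARCH_GRID) if search else {},
            seed=seed,
        ),
        "decision_tree": ModelSpec(
            "decision_tree", {"criterion": "gini", "max_depth": None}, seed=seed
        ),
        "knn": ModelSpec(
            "knn",
            {"n_neighbors": 5, "metric": "euclidean", "weights": "uniform"},
            param_grid={"n_neighbors": list(range(3, 11))} if search else {},
            seed=seed,
        ),
        "svm": ModelSpec(
            "svm",
            {"kernel": "rbf", "gamma": "scale", "C": 1.0},
            param_grid={"C": [0.1, 1.0, 10.0, 100.0]} if search else {},
            seed=seed,
        ),
        # liblinear applies L2 regularization by default
        "logistic_regression": ModelSpec(
            "logistic_regression",
            {"solver": "liblinear", "C": 1.0},
            param_grid={"C": [0.1, 1.0, 10.0, 100.0]} if search else {},
            seed=seed,
        ),
    }


_SCALED = {"knn", "svm", "logistic_regression"}


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparams)
    if spec.name == "random_forest":
        est = RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    elif spec.name == "xgboost":
        est = XGBClassifier(random_state=spec.seed, n_jobs=1, **hp)
    elif spec.name == "decision_tree":
        est = DecisionTreeClassifier(random_state=spec.seed, **hp)
    elif spec.name == "knn":
        est = KNeighborsClassifier(**hp)
    elif spec.name == "svm":
        est = SVC(random_state=spec.seed, **hp)
    else:
        est = LogisticRegression(random_state=spec.seed, **hp)
    if spec.name in _SCALED:
        grid = {f"clf__{k}": v for k, v in spec.param_grid.items()}
        return Pipeline([("scale", StandardScaler()), ("clf", est)]), grid
    return est, dict(spec.param_grid)


@dataclass
class FittedModel:
    """A trained classifier plus the label encoding it was fit with."""

    estimator: object
    feature_columns: list[str]
    negative_label: str
    positive_label: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred = np.asarray(self.estimator.predict(X))
        return np.where(pred == 1, self.positive_label, self.negative_label)

    def score_positive(self, X: np.ndarray) -> np.ndarray:
        """Monotone positive-class confidence (probability or margin)."""
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(X))[:, 1]
        return np.asarray(est.decision_function(X))


def train_model(
    spec: ModelSpec,
    table: FeatureTable,
    train_mask: np.ndarray | None = None,
    positive_label: str = "abnormal",
) -> FittedModel:
    """Fit one classifier on the masked rows of a feature table.

    Labels are binary-encoded with ``positive_label`` → 1.  When the spec
    carries a parameter grid, the grid is searched by seeded stratified
    3-fold CV on the training rows only.
    """
    if train_mask is None:
        train_mask = np.ones(len(table), dtype=bool)
    X = table.X[train_mask]
    y_raw = table.y[train_mask]
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("training rows contain a single class")
    if len(classes) > 2:
        raise ValueError("only binary classification is supported")
    negative = [c for c in classes if c != positive_label]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from data")
    y = (y_raw == positive_label).astype(int)

    est, grid = _make_estimator(spec)
    if grid:
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=spec.seed)
        est = GridSearchCV(est, grid, cv=cv, scoring="accuracy", n_jobs=1)
    est.fit(X, y)
    return FittedModel(
        estimator=est,
        feature_columns=table.feature_columns,
        negative_label=str(negative[0]),
        positive_label=positive_label,
    )


# ---------------------------------------------------------------------------
# metrics

def roc_sweep(
    y_true: Sequence, y_score: Sequence, positive_label
) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve by explicit threshold sweep (ties collapsed).

    Returns (fpr, tpr) starting at (0, 0) and ending at (1, 1).
    """
    y = np.asarray(y_true) == positive_label
    s = np.asarray(y_score, dtype=float)
    if len(y) != len(s):
        raise ValueError("y_true and y_score must have equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # one operating point per distinct threshold: last index of each tie group
    last = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([last, [len(s_sorted) - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg])
    return fpr, tpr


def auc_from_roc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under the ROC by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    y_score: Sequence | None = None,
    positive_label: str = "abnormal",
) -> dict:
    """Accuracy, macro precision/recall/F1, AUC, confusion counts.

    The 2×2 confusion counts take ``positive_label`` (distracted walking)
    as the positive class.  AUC is ``nan`` when scores are absent or only
    one class is present.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    accuracy = float(np.mean(y_true == y_pred))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    confusion = {
        "tp": int(np.sum(pos_t & pos_p)),
        "fn": int(np.sum(pos_t & ~pos_p)),
        "fp": int(np.sum(~pos_t & pos_p)),
        "tn": int(np.sum(~pos_t & ~pos_p)),
    }
    auc = float("nan")
    roc = None
    if y_score is not None and 0 < pos_t.sum() < len(y_true):
        fpr, tpr = roc_sweep(y_true, y_score, positive_label)
        auc = auc_from_roc(fpr, tpr)
        roc = (fpr.tolist(), tpr.tolist())
    return {
        "accuracy": accuracy,
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "auc": auc,
        "confusion": confusion,
        "roc": roc,
    }


@dataclass
class EvalReport:
    """Per-unit (subject or fold) and aggregate classification metrics."""

    protocol: str
    model: str
    per_subject: dict[str, dict] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def finalize(self) -> "EvalReport":
        """Aggregate = unweighted mean over units; confusion counts summed."""
        keys = ("accuracy", "precision", "recall", "f1", "auc")
        agg: dict = {}
        units = list(self.per_subject.values())
        if units:
            for k in keys:
                vals = [u[k] for u in units if np.isfinite(u[k])]
                agg[k] = float(np.mean(vals)) if vals else float("nan")
            agg["confusion"] = {
                c: int(sum(u["confusion"][c] for u in units))
                for c in ("tp", "fn", "fp", "tn")
            }
            agg["n_units"] = len(units)
        self.aggregate = agg
        return self

    def to_dict(self) -> dict:
        def clean(unit: dict) -> dict:
            return {k: v for k, v in unit.items() if k != "roc"}

        return {
            "protocol": self.protocol,
            "model": self.model,
            "per_subject": {k: clean(v) for k, v in self.per_subject.items()},
            "aggregate": self.aggregate,
            "skipped": list(self.skipped),
        }

    @property
    def roc_points(self) -> dict[str, tuple]:
        return {
            k: tuple(v["roc"])
            for k, v in self.per_subject.items()
            if v.get("roc") is not None
        }


def _fit_score(
    spec: ModelSpec,
    table: FeatureTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    positive_label: str,
) -> dict:
    if np.intersect1d(train_idx, test_idx).size:
        raise AssertionError("train/test leakage: overlapping rows")
    mask = np.zeros(len(table), dtype=bool)
    mask[train_idx] = True
    model = train_model(spec, table, mask, positive_label)
    X_test = table.X[test_idx]
    y_test = table.y[test_idx]
    metrics = compute_metrics(
        y_test,
        model.predict(X_test),
        model.score_positive(X_test),
        positive_label,
    )
    metrics["n_test"] = int(len(test_idx))
    return metrics


def evaluate_personalized(
    spec: ModelSpec,
    table: FeatureTable,
    split: float = 0.8,
    seed: int = 0,
    positive_label: str = "abnormal",
) -> EvalReport:
    """Within-subject evaluation: one model per subject on its own windows.

    Each subject's windows get a stratified ``split``/(1−split) train/test
    partition; subjects lacking one of the classes are skipped and listed
    in the report.
    """
    report = EvalReport(protocol="personalized", model=spec.name)
    rng = np.random.default_rng(seed)
    for subject in sorted(pd.unique(table.groups)):
        idx = np.nonzero(table.groups == subject)[0]
        y = table.y[idx]
        rs = int(rng.integers(2**31))
        if len(np.unique(y)) < 2:
            report.skipped.append(subject)
            continue
        tr, te = train_test_split(
            idx, train_size=split, stratify=y, random_state=rs
        )
        report.per_subject[subject] = _fit_score(spec, table, tr, te, positive_label)
    return report.finalize()


def evaluate_loso(
    spec: ModelSpec,
    table: FeatureTable,
    positive_label: str = "abnormal",
) -> EvalReport:
    """Leave-one-subject-out evaluation of a single generalized model."""
    subjects = sorted(pd.unique(table.groups))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    report = EvalReport(protocol="loso", model=spec.name)
    for subject in subjects:
        te = np.nonzero(table.groups == subject)[0]
        tr = np.nonzero(table.groups != subject)[0]
        report.per_subject[subject] = _fit_score(spec, table, tr, te, positive_label)
    return report.finalize()


def evaluate_ei(
    table: FeatureTable,
    subset: str,
    spec: ModelSpec,
    trait_map: Mapping[str, str] | None = None,
    n_folds: int = 5,
    positive_label: str = "I",
) -> EvalReport:
    """Subject-grouped cross-validation of E/I trait classification.

    ``table`` must carry E/I labels (or pass ``trait_map`` to relabel by
    subject).  Subjects are dealt into ``n_folds`` groups in sorted order
    so no subject appears in both train and test of a fold.
    """
    if trait_map is not None:
        table = with_trait_labels(table, dict(trait_map))
    table = FeatureTable(table.df, subset)
    traits = set(table.y)
    if not {"E", "I"} <= traits:
        raise ValueError("both E and I traits must be present")
    subjects = sorted(pd.unique(table.groups))
    n_folds = min(n_folds, len(subjects))
    if n_folds < 2:
        raise ValueError("need at least 2 subject groups")
    report = EvalReport(protocol=f"ei_{subset}", model=spec.name)
    for fold in range(n_folds):
        held = set(subjects[fold::n_folds])
        te = np.nonzero([g in held for g in table.groups])[0]
        tr = np.nonzero([g not in held for g in table.groups])[0]
        if len(np.unique(table.y[tr])) < 2 or len(te) == 0:
            report.skipped.append(f"fold{fold}")
            continue
        report.per_subject[f"fold{fold}"] = _fit_score(
            spec, table, tr, te, positive_label
        )
    return report.finalize()


def compare_ei(
    table: FeatureTable,
    spec: ModelSpec,
    trait_map: Mapping[str, str] | None = None,
    n_folds: int = 5,
) -> dict[str, EvalReport]:
    """Paired accelerometer-only vs multi-sensor E/I comparison."""
    return {
        subset: evaluate_ei(table, subset, spec, trait_map, n_folds)
        for subset in ("accel_only", "multi_sensor")
    }


def shuffle_labels_within_subject(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Permute labels independently within each subject (null calibration)."""
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for subject in sorted(pd.unique(df["subject_id"])):
        sel = df["subject_id"] == subject
        df.loc[sel, "label"] = rng.permutation(df.loc[sel, "label"].to_numpy())
    return FeatureTable(df, table.feature_subset)
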