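import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from gaitsense.classify import (
    MODEL_NAMES,
    ModelSpec,
    auc_from_roc,
    compute_metrics,
    default_model_specs,
    evaluate_ei,
    evaluate_loso,
    evaluate_personalized,
    roc_sweep,
    shuffle_labels_within_subject,
    train_model,
)
from gaitsense.features import MULTI_SENSOR_FEATURES, FeatureTable


def _toy_table(n_per_class=30, n_subjects=2, gap=5.0, seed=0):
    """Two well-separated Gaussian clusters, split across subjects."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for label, mu in (("normal", 0.0), ("abnormal", gap)):
            for i in range(n_per_class):
                base = rng.normal(mu, 1.0, len(MULTI_SENSOR_FEATURES))
                rows.append({
                    "subject_id": f"S{s + 1:02d}",
                    "condition": "pocket" if label == "normal" else "look",
                    "rep": 1,
                    "window_index": i,
                    **dict(zip(MULTI_SENSOR_FEATURES, np.abs(base))),
                    "label": label,
                })
    return FeatureTable(pd.DataFrame(rows), "multi_sensor")


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        # TP=97 FN=3 FP=19 TN=81 out of 200
        y_true = ["abnormal"] * 100 + ["normal"] * 100
        y_pred = (["abnormal"] * 97 + ["normal"] * 3
                  + ["abnormal"] * 19 + ["normal"] * 81)
        m = compute_metrics(y_true, y_pred)
        assert m["confusion"] == {"tp": 97, "fn": 3, "fp": 19, "tn": 81}
        assert m["accuracy"] == pytest.approx(178 / 200)
        prec_abnormal = m["confusion"]["tp"] / (
            m["confusion"]["tp"] + m["confusion"]["fp"]
        )
        assert prec_abnormal == pytest.approx(0.836, abs=5e-4)
        recall_abnormal = 97 / 100
        assert recall_abnormal == pytest.approx(0.97)

    def test_perfect_scores_give_unit_auc(self):
        y = ["normal", "abnormal", "normal", "abnormal"]
        m = compute_metrics(y, y, [0.1, 0.9, 0.2, 0.8])
        assert m["auc"] == 1.0

    def test_constant_scores_give_half_auc(self):
        y = ["normal"] * 10 + ["abnormal"] * 10
        m = compute_metrics(y, y, np.full(20, 0.5))
        assert m["auc"] == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["normal"], ["normal", "abnormal"])


def test_auc_equals_normalized_mann_whitney(rng):
    """The threshold-sweep trapezoid AUC is the Mann-Whitney U statistic
    divided by n+ * n- (ties included) on arbitrary score sets."""
    for trial in range(30):
        n_pos = int(rng.integers(2, 20))
        n_neg = int(rng.integers(2, 20))
        scores = rng.normal(size=n_pos + n_neg)
        if trial % 3 == 0:
            scores = np.round(scores, 1)  # force ties
        y = np.array(["abnormal"] * n_pos + ["normal"] * n_neg)
        fpr, tpr = roc_sweep(y, scores, "abnormal")
        auc = auc_from_roc(fpr, tpr)
        u = mannwhitneyu(scores[:n_pos], scores[n_pos:]).statistic
        assert abs(auc - u / (n_pos * n_neg)) < 1e-12


class TestTrainModel:
    def test_separable_toy_is_memorized_by_tree(self):
        table = _toy_table()
        spec = default_model_specs()["decision_tree"]
        model = train_model(spec, table)
        acc = np.mean(model.predict(table.X) == table.y)
        assert acc == 1.0

    def test_xgboost_fixed_seed_determinism(self):
        table = _toy_table(gap=1.0)
        spec = default_model_specs(seed=42)["xgboost"]
        a = train_model(spec, table).score_positive(table.X)
        b = train_model(spec, table).score_positive(table.X)
        np.testing.assert_array_equal(a, b)

    def test_random_forest_documented_settings(self):
        spec = default_model_specs()["random_forest"]
        assert spec.hyperparams == {"n_estimators": 100, "max_depth": None}

    def test_single_class_rejected(self):
        table = _toy_table()
        mask = table.y == "normal"
        spec = default_model_specs()["decision_tree"]
        with pytest.raises(ValueError, match="single class"):
            train_model(spec, table, mask)

    def test_out_of_range_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("knn", {"n_neighbors": 2})
        with pytest.raises(ValueError):
            ModelSpec("svm", {"C": 1000.0})

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_every_model_fits_and_scores(self, name):
        table = _toy_table(n_per_class=15)
        model = train_model(default_model_specs()[name], table)
        scores = model.score_positive(table.X)
        assert len(scores) == len(table)
        m = compute_metrics(table.y, model.predict(table.X), scores)
        assert m["auc"] > 0.95  # separable by construction


class TestPersonalized:
    def test_split_counting_and_report_shape(self, small_table):
        spec = default_model_specs()["decision_tree"]
        report = evaluate_personalized(spec, small_table, split=0.8, seed=3)
        assert report.protocol == "personalized"
        assert len(report.per_subject) == 6
        for unit in report.per_subject.values():
            assert unit["n_test"] == 54  # 270 windows per subject, 20% held out
            assert sum(unit["confusion"].values()) == unit["n_test"]
        agg = report.aggregate
        assert all(0.0 <= agg[k] <= 1.0
                   for k in ("accuracy", "precision", "recall", "f1", "auc"))

    def test_subject_missing_a_class_is_skipped(self, small_table):
        df = small_table.df.copy()
        df.loc[df.subject_id == "S01", "label"] = "normal"
        spec = default_model_specs()["decision_tree"]
        report = evaluate_personalized(spec, FeatureTable(df, "accel_only"))
        assert report.skipped == ["S01"]
        assert len(report.per_subject) == 5

    def test_reports_reproducible(self, small_table):
        spec = default_model_specs()["xgboost"]
        a = evaluate_personalized(spec, small_table, seed=9).to_dict()
        b = evaluate_personalized(spec, small_table, seed=9).to_dict()
        assert a == b

    def test_label_shuffled_null_is_uninformative(self, small_table):
        spec = default_model_specs()["decision_tree"]
        null = shuffle_labels_within_subject(small_table, seed=21)
        report = evaluate_personalized(spec, null, seed=21)
        assert abs(report.aggregate["auc"] - 0.5) < 0.1


class TestLoso:
    def test_fold_structure(self, small_table):
        spec = default_model_specs()["decision_tree"]
        report = evaluate_loso(spec, small_table)
        assert report.protocol == "loso"
        assert len(report.per_subject) == 6
        per_subject_rows = small_table.df.groupby("subject_id").size()
        for subject, unit in report.per_subject.items():
            assert unit["n_test"] == per_subject_rows[subject]

    def test_requires_two_subjects(self, small_table):
        df = small_table.df[small_table.df.subject_id == "S01"]
        spec = default_model_specs()["decision_tree"]
        with pytest.raises(ValueError):
            evaluate_loso(spec, FeatureTable(df, "accel_only"))


class TestEvaluateEi:
    def test_multi_sensor_uses_nine_features(self, small_table,
                                             small_trait_map):
        spec = default_model_specs()["decision_tree"]
        report = evaluate_ei(small_table, "multi_sensor", spec,
                             trait_map=small_trait_map, n_folds=3)
        assert report.protocol == "ei_multi_sensor"
        assert len(report.per_subject) >= 2

    def test_missing_trait_class_rejected(self, small_table):
        all_e = {s: "E" for s in set(small_table.df.subject_id)}
        spec = default_model_specs()["decision_tree"]
        with pytest.raises(ValueError, match="E and I"):
            evaluate_ei(small_table, "accel_only", spec, trait_map=all_e)

    def test_no_subject_in_both_train_and_test(self, small_table,
                                               small_trait_map, monkeypatch):
        import gaitsense.classify as cl

        seen = []
        orig = cl._fit_score

        def spy(spec, table, tr, te, pos):
            seen.append((set(table.groups[tr]), set(table.groups[te])))
            return orig(spec, table, tr, te, pos)

        monkeypatch.setattr(cl, "_fit_score", spy)
        spec = default_model_specs()["decision_tree"]
        evaluate_ei(small_table, "accel_only", spec,
                    trait_map=small_trait_map, n_folds=3)
        assert seen
        for train_subjects, test_subjects in seen:
            assert not train_subjects & test_subjects
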