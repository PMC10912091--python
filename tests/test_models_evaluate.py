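"""Model zoo, LOSO folds, metrics, and the experiment loop."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from adspect.errors import DesignError, ParameterError
from adspect.evaluate import (
    accuracy_kappa,
    chance_upper_bound,
    confusion,
    f1_vs_nfeatures,
    fit_predict,
    loso_folds,
    per_class_metrics,
    roc_auc,
    run_experiment,
)
from adspect.features import FeatureTable
from adspect.models import MODEL_NAMES, make_model
from adspect.schemes import CLASS_ORDER


class TestModels:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_factory_builds_every_model(self, name):
        est = make_model(name, seed=0)
        assert hasattr(est, "fit") and hasattr(est, "predict_proba")

    def test_unknown_name(self):
        with pytest.raises(ParameterError):
            make_model("forest")

    def test_knn_nearest_duplicate(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        y = [0, 1, 2]
        model = make_model("cKNN", n_neighbors=1)
        model.fit(X, y)
        proba = model.predict_proba(np.array([[0.0, 1.0]]))
        assert model.predict([[0.0, 1.0]])[0] == 1
        assert proba[0, list(model.classes_).index(1)] == 1.0

    def test_cosine_knn_scale_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6)) + 2.0
        y = rng.integers(0, 4, 40)
        test = rng.standard_normal((5, 6)) + 2.0
        model = make_model("cKNN", n_neighbors=5)
        base = model.fit(X, y).predict(test)
        rescaled = test.copy()
        rescaled[2] *= 13.0  # positive rescaling of one subject's feature vector
        np.testing.assert_array_equal(model.predict(rescaled), base)

    def test_lda_separates_spherical_gaussians(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        y = np.array([0] * 100 + [1] * 100)
        test_X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(10, 1, (50, 2))])
        test_y = np.array([0] * 50 + [1] * 50)
        model = make_model("LDA").fit(X, y)
        assert (model.predict(test_X) == test_y).mean() == 1.0


class TestFolds:
    def test_58_subjects_58_folds(self):
        ids = [f"sub{i:03d}" for i in range(1, 59)]
        folds = loso_folds(ids)
        assert len(folds) == 58
        tested = [test for _, test in folds]
        assert sorted(tested) == sorted(ids)  # each subject tested exactly once
        for train, test in folds:
            assert test not in train
            assert sorted(train + [test]) == sorted(ids)

    def test_duplicate_ids_refused(self):
        with pytest.raises(DesignError):
            loso_folds(["a", "a", "b"])


class TestConfusionAndMetrics:
    def test_perfect_predictions_diagonal(self):
        y = ["SCD", "naMCI", "aMCI", "AD"]
        cm = confusion(y, y)
        assert np.array_equal(cm, np.eye(4, dtype=int))

    def test_off_diagonal_placement(self):
        cm = confusion(["SCD", "SCD"], ["SCD", "AD"])
        np.testing.assert_array_equal(cm[0], [1, 0, 0, 1])
        assert cm.sum() == 2

    def test_table5_style_sensitivities(self):
        """19/20 SCD and 8/10 naMCI correct give 95.00% and 80.00% sensitivity."""
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0], cm[0, 2] = 19, 1
        cm[1, 1], cm[1, 0] = 8, 2
        cm[2, 2], cm[3, 3] = 18, 10
        assert per_class_metrics(cm, 0)["sensitivity"] == pytest.approx(95.00)
        assert per_class_metrics(cm, 1)["sensitivity"] == pytest.approx(80.00)

    def test_diagonal_cm_all_metrics_100(self):
        cm = np.diag([20, 10, 18, 10])
        for i in range(4):
            m = per_class_metrics(cm, i)
            for key in ("sensitivity", "specificity", "precision", "f1"):
                assert m[key] == pytest.approx(100.0)

    def test_metrics_against_sklearn(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        cm = confusion(y_true, y_pred)
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0
        )
        for i in range(4):
            m = per_class_metrics(cm, i)
            assert m["sensitivity"] == pytest.approx(rec[i] * 100, abs=1e-9)
            assert m["precision"] == pytest.approx(prec[i] * 100, abs=1e-9)
            assert m["f1"] == pytest.approx(f1[i] * 100, abs=1e-9)

    def test_harmonic_mean_identity(self):
        rng = np.random.default_rng(3)
        cm = rng.integers(0, 20, (4, 4))
        for i in range(4):
            m = per_class_metrics(cm, i)
            p, s = m["precision"], m["sensitivity"]
            if p + s > 0:
                assert m["f1"] == pytest.approx(2 * p * s / (p + s), abs=1e-9)

    def test_accuracy_kappa_anchors(self):
        acc, kappa = accuracy_kappa(np.diag([5, 5, 5, 5]))
        assert acc == 100.0 and kappa == pytest.approx(1.0)
        # rows identical: prediction independent of truth -> kappa 0
        acc, kappa = accuracy_kappa(np.full((4, 4), 3))
        assert kappa == pytest.approx(0.0)

    def test_accuracy_kappa_hand_case(self):
        acc, kappa = accuracy_kappa(np.array([[3, 1], [1, 3]]))
        assert acc == pytest.approx(75.0)     # p_o = 0.75
        assert kappa == pytest.approx(0.5)    # p_e = 0.5

    def test_kappa_against_sklearn(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 4, 80)
        y_pred = rng.integers(0, 4, 80)
        _, kappa = accuracy_kappa(confusion(y_true, y_pred))
        assert kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)


class TestRocAuc:
    def _scores(self, col):
        scores = np.zeros((len(col), 4))
        scores[:, 0] = col
        return scores

    def test_perfect_ranking(self):
        y = [0, 0, 1, 2]
        assert roc_auc(y, self._scores([0.9, 0.8, 0.2, 0.1]), 0) == 1.0

    def test_constant_scores_give_half(self):
        y = [0, 0, 1, 2]
        assert roc_auc(y, self._scores([0.5] * 4), 0) == pytest.approx(0.5)

    def test_concordant_pair_count(self):
        """3 positives (0.9, 0.8, 0.4) vs 3 negatives (0.7, 0.3, 0.2): AUC = 8/9."""
        y = [0, 0, 0, 1, 1, 1]
        scores = self._scores([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        assert roc_auc(y, scores, 0) == pytest.approx(8.0 / 9.0)


def toy_tables(n_per_group=5, n_features=12, seed=0, separation=3.0):
    """Separable 4-class table: group-dependent means on a few columns."""
    rng = np.random.default_rng(seed)
    ids, labels, rows = [], [], []
    for gi, group in enumerate(CLASS_ORDER):
        for k in range(n_per_group):
            ids.append(f"{group}{k}")
            labels.append(group)
            row = rng.standard_normal(n_features)
            row[:3] += separation * gi
            rows.append(row)
    values = pd.DataFrame(np.array(rows), index=ids,
                          columns=[f"enc1.k{i}" for i in range(n_features)])
    return FeatureTable(values, pd.Series(labels, index=ids), "enc1")


class TestExperiment:
    def test_fit_predict_scores_sum_to_one(self):
        table = toy_tables()
        X = table.values.to_numpy()
        y = list(table.labels)
        pred, scores = fit_predict("cKNN", X[:-1], y[:-1], X[-1:])
        assert scores.shape == (1, 4)
        assert scores.sum() == pytest.approx(1.0)

    def test_fit_predict_refuses_empty_features(self):
        with pytest.raises(ParameterError):
            fit_predict("LDA", np.empty((10, 0)), ["SCD"] * 10, np.empty((1, 0)))

    def test_separable_table_scores_perfectly(self):
        reports = run_experiment({"enc1": toy_tables(separation=8.0)},
                                 models=("LDA",), seed=0)
        rep = reports[("LDA", "enc1")]
        assert rep.accuracy == 100.0 and rep.kappa == pytest.approx(1.0)

    def test_determinism_same_seed(self):
        table = toy_tables(separation=1.0)
        a = run_experiment({"enc1": table}, models=("cKNN", "narNN"), seed=5)
        b = run_experiment({"enc1": table}, models=("cKNN", "narNN"), seed=5)
        for key in a:
            assert a[key].predicted_labels == b[key].predicted_labels
            np.testing.assert_array_equal(a[key].scores, b[key].scores)

    def test_report_serializes(self):
        import json

        reports = run_experiment({"enc1": toy_tables()}, models=("cKNN",), seed=0)
        payload = json.dumps(reports[("cKNN", "enc1")].to_dict())
        assert "confusion_matrix" in payload

    def test_paper_mode_runs(self):
        reports = run_experiment({"enc1": toy_tables()}, models=("cKNN",),
                                 mode="paper", seed=0)
        assert ("cKNN", "enc1") in reports

    def test_unknown_model_and_mode(self):
        with pytest.raises(ParameterError):
            run_experiment({"enc1": toy_tables()}, models=("bogus",))
        with pytest.raises(ParameterError):
            run_experiment({"enc1": toy_tables()}, models=("cKNN",), mode="loose")


class TestF1VsNFeatures:
    def test_k_zero_refused(self):
        with pytest.raises(ParameterError):
            f1_vs_nfeatures(toy_tables(), k_grid=(0,))

    def test_full_feature_count_matches_run_experiment(self):
        """Using all features reproduces the run with an all-pass screen."""
        table = toy_tables(separation=1.5)
        curve = f1_vs_nfeatures(table, "cKNN", k_grid=(table.n_features,), seed=1)
        full = run_experiment({"enc1": table}, models=("cKNN",), seed=1, alpha=1.0)
        assert curve[table.n_features] == pytest.approx(
            full[("cKNN", "enc1")].macro_f1
        )

    def test_curve_has_requested_grid(self):
        curve = f1_vs_nfeatures(toy_tables(), "cKNN", k_grid=(1, 3, 5), seed=0)
        assert sorted(curve) == [1, 3, 5]
        assert all(0.0 <= v <= 100.0 for v in curve.values())


def test_chance_upper_bound_matches_binomial():
    labels = ["SCD"] * 20 + ["naMCI"] * 10 + ["aMCI"] * 18 + ["AD"] * 10
    from scipy import stats

    expected = stats.binom.ppf(0.95, 58, 20 / 58) / 58
    assert chance_upper_bound(labels) == pytest.approx(expected)
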