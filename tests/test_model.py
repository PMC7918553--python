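"""Training protocol: metrics, splits, grid search, bundles, learning curves."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef
from sklearn.model_selection import ParameterGrid

import zincsite as z
from zincsite.model import DEFAULT_PARAM_GRID, metrics_from_predictions

from conftest import TINY_GRID


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = z.compute_metrics(50, 50, 0, 0)
        assert (m.recall, m.precision, m.f1, m.mcc) == (1.0, 1.0, 1.0, 1.0)
        assert not m.degenerate

    def test_all_positive_predictor_has_zero_mcc(self):
        m = z.compute_metrics(50, 0, 50, 0)
        assert m.mcc == 0.0
        assert m.degenerate  # tn+fn = 0 denominator

    def test_hand_computed_confusion(self):
        m = z.compute_metrics(45, 40, 10, 5)
        assert m.recall == pytest.approx(45 / 50)
        assert m.precision == pytest.approx(45 / 55)
        p, r = 45 / 55, 45 / 50
        assert m.f1 == pytest.approx(2 * p * r / (p + r))
        assert m.mcc == pytest.approx(
            (45 * 40 - 10 * 5) / math.sqrt(55 * 50 * 50 * 45))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            z.compute_metrics(-1, 1, 1, 1)

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 100, 4)
            m = z.compute_metrics(tp, tn, fp, fn)
            assert m.f1 == pytest.approx(
                2 / (1 / m.recall + 1 / m.precision))

    def test_mcc_class_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            a = z.compute_metrics(tp, tn, fp, fn).mcc
            b = z.compute_metrics(tn, tp, fn, fp).mcc
            assert a == pytest.approx(b)

    def test_agrees_with_sklearn_on_random_labels(self):
        """Independent library oracle on raw label/prediction vectors."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            y = rng.integers(0, 2, 60)
            pred = rng.integers(0, 2, 60)
            m = metrics_from_predictions(y, pred)
            assert m.f1 == pytest.approx(f1_score(y, pred, zero_division=0))
            if not m.degenerate:
                assert m.mcc == pytest.approx(matthews_corrcoef(y, pred))


class TestSplit:
    def test_stratified_20_80(self, seq_dataset):
        train, test = z.split_train_test(seq_dataset, seed=0)
        assert len(train) == 64 and len(test) == 16
        assert train.n_positive == train.n_negative == 32
        assert test.n_positive == test.n_negative == 8

    def test_disjoint_and_reproducible(self, seq_dataset):
        a_train, a_test = z.split_train_test(seq_dataset, seed=4)
        b_train, b_test = z.split_train_test(seq_dataset, seed=4)
        pd.testing.assert_frame_equal(a_train.X, b_train.X)
        pd.testing.assert_frame_equal(a_test.X, b_test.X)
        merged = pd.concat([a_train.provenance, a_test.provenance])
        assert len(merged) == len(seq_dataset)
        assert not merged.duplicated().any()

    def test_too_small_dataset(self, seq_dataset):
        with pytest.raises(ValueError):
            z.split_train_test(seq_dataset.subset(np.arange(3)), seed=0)


class TestGridSearch:
    def test_default_grid_has_48_combinations(self):
        assert len(ParameterGrid(DEFAULT_PARAM_GRID)) == 48
        assert sorted(DEFAULT_PARAM_GRID["criterion"]) == ["entropy", "gini"]
        assert sorted(DEFAULT_PARAM_GRID["n_estimators"]) == [10, 100, 1000]
        assert len(DEFAULT_PARAM_GRID["max_depth"]) == 4
        assert None in DEFAULT_PARAM_GRID["max_depth"]
        assert sorted(DEFAULT_PARAM_GRID["max_features"]) == ["log2", "sqrt"]

    def test_single_combination_grid(self, seq_dataset):
        train, _ = z.split_train_test(seq_dataset, seed=0)
        grid = {"criterion": ["gini"], "max_depth": [4],
                "n_estimators": [10], "max_features": ["sqrt"]}
        params, results = z.grid_search(train, grid=grid, seed=0)
        assert params == {"criterion": "gini", "max_depth": 4,
                          "n_estimators": 10, "max_features": "sqrt"}
        assert len(results) == 1

    def test_separable_data_reaches_f1_one(self, seq_dataset):
        train, _ = z.split_train_test(seq_dataset, seed=0)
        _, results = z.grid_search(train, grid=TINY_GRID, seed=0)
        assert results["mean_f1"].max() == pytest.approx(1.0)

    def test_selection_is_argmax_mean_f1(self, seq_dataset):
        train, _ = z.split_train_test(seq_dataset, seed=1)
        grid = {"criterion": ["gini", "entropy"], "max_depth": [2, None],
                "n_estimators": [5], "max_features": ["sqrt"]}
        params, results = z.grid_search(train, grid=grid, k=5, seed=1)
        best_row = results.loc[results["mean_f1"].idxmax()]
        assert params["criterion"] == best_row["criterion"]
        assert results["n_folds"].eq(5).all()

    def test_single_class_training_rejected(self, seq_dataset):
        idx = np.where(seq_dataset.y == 1)[0]
        with pytest.raises(ValueError):
            z.grid_search(seq_dataset.subset(idx), grid=TINY_GRID, seed=0)


class TestBundle:
    def test_memorizes_training_set(self, seq_bundle, seq_dataset):
        train, _ = z.split_train_test(seq_dataset, seed=11)
        metrics = z.evaluate(seq_bundle, train)
        assert metrics.recall >= 0.95

    def test_fixed_seed_identical_predictions(self, seq_dataset):
        train, test = z.split_train_test(seq_dataset, seed=2)
        a = z.train_final(train, {"n_estimators": 20}, seed=2)
        b = z.train_final(train, {"n_estimators": 20}, seed=2)
        X = test.X.to_numpy(float)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_persistence_round_trip(self, seq_bundle, seq_dataset, tmp_path):
        path = tmp_path / "model.bundle"
        seq_bundle.save(path)
        back = z.ModelBundle.load(path)
        assert back.family == "C2H2" and back.modality == "sequence"
        X = seq_dataset.X.to_numpy(float)
        np.testing.assert_array_equal(back.predict(X), seq_bundle.predict(X))
        np.testing.assert_allclose(
            back.predict_proba_positive(X), seq_bundle.predict_proba_positive(X))

    def test_load_rejects_foreign_files(self, tmp_path):
        import joblib
        path = tmp_path / "junk.bundle"
        joblib.dump({"format": "something-else"}, path)
        with pytest.raises(ValueError, match="not a zincsite"):
            z.ModelBundle.load(path)

    def test_schema_mismatch_rejected(self, seq_bundle, struct_dataset):
        with pytest.raises(ValueError):
            z.evaluate(seq_bundle, struct_dataset)

    def test_empty_test_set_rejected(self, seq_bundle, seq_dataset):
        with pytest.raises(ValueError):
            z.evaluate(seq_bundle, seq_dataset.subset(np.array([], dtype=int)))


class TestEstimator:
    def test_fit_sets_sklearn_attributes(self, seq_dataset):
        clf = z.ZincSiteClassifier(param_grid=TINY_GRID, random_state=0)
        clf.fit(seq_dataset.X.to_numpy(float), seq_dataset.y)
        assert hasattr(clf, "best_params_")
        assert clf.n_features_in_ == 9
        assert set(clf.classes_) == {0, 1}
        proba = clf.predict_proba(seq_dataset.X.to_numpy(float))
        assert proba.shape == (len(seq_dataset), 2)

    def test_clone_and_params_round_trip(self):
        from sklearn.base import clone
        clf = z.ZincSiteClassifier(family="H3", cv=3, random_state=7)
        cloned = clone(clf)
        assert cloned.get_params()["family"] == "H3"
        assert cloned.get_params()["cv"] == 3


class TestLearningCurve:
    def test_point_count_and_full_fraction(self, seq_dataset):
        points = z.learning_curve(
            seq_dataset, fractions=(0.5, 1.0), k=3, seed=0,
            params={"n_estimators": 10})
        assert len(points) == 2
        assert points[1][0] == len(seq_dataset)
        assert points[0][0] == 40

    def test_strong_signal_high_mcc_at_full_size(self, seq_dataset):
        points = z.learning_curve(
            seq_dataset, fractions=(1.0,), k=5, seed=0,
            params={"n_estimators": 30})
        assert points[0][1] >= 0.9
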