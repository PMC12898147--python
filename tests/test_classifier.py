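"""Standardization, SMOTE, curve metrics, and the CV grid-search protocol."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from oracles import roc_auc_pairwise
from resistome.classify import (
    balance_with_smote, confusion_at, cv_auc_fixed, cv_grid_search, pr_points,
    roc_points, smote_oversample, undersample_majority, zscore_fit_apply,
)
from resistome.types import ResistomeError


class TestZscore:
    def test_two_point_column(self):
        out, = zscore_fit_apply(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0])

    def test_constant_column_zeroed(self):
        train = np.array([[2.0, 1.0], [2.0, 3.0]])
        t, applied = zscore_fit_apply(train, np.array([[5.0, 9.0]]))
        np.testing.assert_array_equal(t[:, 0], 0.0)
        assert applied[0, 0] == 0.0

    def test_train_statistics_used_for_apply(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(50, 4))
        test = rng.normal(size=(10, 4))
        t, a = zscore_fit_apply(train, test)
        np.testing.assert_allclose(t.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(t.std(axis=0), 1.0, atol=1e-12)
        expected = (test - train.mean(axis=0)) / train.std(axis=0)
        np.testing.assert_allclose(a, expected)


class TestSmote:
    def test_segment_interpolation_in_2d(self):
        rng = np.random.default_rng(1)
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        synth = smote_oversample(minority, 1, 50, rng)
        np.testing.assert_allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert np.all((synth >= 0) & (synth <= 1))

    def test_zero_requested_returns_empty(self):
        rng = np.random.default_rng(2)
        out = smote_oversample(np.array([[0.0], [1.0]]), 1, 0, rng)
        assert out.shape == (0, 1)

    def test_synthetic_points_inside_convex_hull(self):
        rng = np.random.default_rng(3)
        minority = rng.normal(size=(12, 2))
        synth = smote_oversample(minority, 3, 200, rng)
        hull = Delaunay(minority)
        assert np.all(hull.find_simplex(synth) >= 0)

    def test_single_point_rejected(self):
        with pytest.raises(ResistomeError, match="at least 2"):
            smote_oversample(np.array([[1.0, 2.0]]), 1, 5,
                             np.random.default_rng(0))

    def test_k_autoshrunk_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        with caplog.at_level("WARNING"):
            smote_oversample(np.array([[0.0], [1.0], [2.0]]), 10, 5, rng)
        assert "shrunk" in caplog.text

    def test_balance_preserves_originals_verbatim(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        y = np.array([1] * 5 + [0] * 15)
        X_aug, y_aug = balance_with_smote(X, y, 3, rng)
        np.testing.assert_array_equal(X_aug[:20], X)
        np.testing.assert_array_equal(y_aug[:20], y)
        assert int(y_aug.sum()) == 15 and len(y_aug) == 30
        # appended rows are all minority-labelled
        assert np.all(y_aug[20:] == 1)

    def test_undersample_subsets_majority(self):
        rng = np.random.default_rng(6)
        X = np.arange(40, dtype=float).reshape(20, 2)
        y = np.array([1] * 5 + [0] * 15)
        X_u, y_u = undersample_majority(X, y, rng)
        assert len(y_u) == 10 and int(y_u.sum()) == 5
        rows = {tuple(r) for r in X_u}
        assert rows <= {tuple(r) for r in X}


class TestCurves:
    def test_perfect_ranking(self):
        assert roc_points([0.9, 0.1], [1, 0])[3] == 1.0

    def test_all_tied_scores_half_credit(self):
        assert roc_points([0.5] * 10, [1, 0] * 5)[3] == 0.5

    def test_trapezoid_equals_pairwise_u_statistic(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = 200
            probs = np.round(rng.random(n), 2)  # induces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert abs(roc_points(probs, labels)[3]
                       - roc_auc_pairwise(probs, labels)) < 1e-12

    def test_pr_auc_bounds_and_perfect_case(self):
        _, _, _, auc = pr_points([0.9, 0.8, 0.1], [1, 1, 0])
        assert auc == 1.0
        _, _, _, auc2 = pr_points([0.5] * 8, [1, 0] * 4)
        assert 0.0 <= auc2 <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ResistomeError):
            roc_points([0.5, 0.6], [1, 1])

    def test_confusion_threshold_is_inclusive(self):
        c = confusion_at([0.5, 0.49], [1, 0])
        assert c == {"tp": 1, "fp": 0, "tn": 1, "fn": 0}


def separable_data(seed, n=60, n_features=4, imbalance=0.5):
    rng = np.random.default_rng(seed)
    n_pos = int(n * imbalance)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X = rng.normal(size=(n, n_features)) + 4.0 * y[:, None]
    return X, y


class TestCvGridSearch:
    def test_separable_data_near_perfect_auc(self):
        X, y = separable_data(0)
        report = cv_grid_search(X, y, grid=[{"n_estimators": 100}], seed=1)
        assert report.roc_auc_mean >= 0.99
        assert report.pr_auc_mean >= 0.99

    def test_confusion_counts_sum_to_n(self):
        X, y = separable_data(1, imbalance=0.3)
        report = cv_grid_search(X, y, grid=[{"n_estimators": 50}], seed=2)
        assert sum(report.confusion.values()) == len(y)

    def test_out_of_fold_predictions_cover_every_sample(self):
        X, y = separable_data(2)
        report = cv_grid_search(X, y, grid=[{"n_estimators": 50}], seed=3)
        assert report.oof_probs.shape == y.shape
        assert not np.isnan(report.oof_probs).any()

    def test_importances_normalized(self):
        X, y = separable_data(3)
        report = cv_grid_search(X, y, grid=[{"n_estimators": 50}], seed=4,
                                genes=list("abcd"))
        assert np.all(report.importances >= 0)
        assert abs(report.importances.sum() - 1.0) < 1e-9

    def test_grid_winner_reported(self):
        X, y = separable_data(4)
        grid = [{"n_estimators": 20}, {"n_estimators": 60}]
        report = cv_grid_search(X, y, grid=grid, seed=5)
        assert report.best_params in grid

    def test_too_small_class_rejected(self):
        X, y = separable_data(5)
        y = np.zeros_like(y)
        y[:3] = 1
        with pytest.raises(ResistomeError, match="folds"):
            cv_grid_search(X, y, grid=[{"n_estimators": 20}], n_folds=5, seed=0)

    def test_imbalanced_data_exercises_smote(self):
        X, y = separable_data(6, n=80, imbalance=0.2)
        report = cv_grid_search(X, y, grid=[{"n_estimators": 100}], seed=7,
                                use_smote=True)
        assert report.roc_auc_mean >= 0.95

    def test_undersampling_mode_runs(self):
        X, y = separable_data(7, n=80, imbalance=0.25)
        auc = cv_auc_fixed(X, y, seed=8, use_smote=False, n_estimators=50)
        report = cv_grid_search(X, y, grid=[{"n_estimators": 50}], seed=8,
                                undersample=True)
        assert report.roc_auc_mean >= 0.9 and auc >= 0.9
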