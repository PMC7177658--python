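"""Metrics, PR curves, cross-validation, grid search."""

import numpy as np
import pandas as pd
import pytest

from acrboost.evaluation import (
    ConfusionCounts,
    classification_metrics,
    confusion_counts,
    grid_search,
    pr_curve,
    repeated_stratified_cv,
)


def ap_bruteforce(y, s):
    """Step-wise average precision by explicit threshold enumeration."""
    y = np.asarray(y, int)
    s = np.asarray(s, float)
    ap, prev_r = 0.0, 0.0
    for th in sorted(set(s), reverse=True):
        pred = s >= th
        tp = int(np.sum(y & pred))
        fp = int(np.sum(~y.astype(bool) & pred))
        p = tp / (tp + fp)
        r = tp / int(np.sum(y))
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestClassificationMetrics:
    def test_hand_worked_counts(self):
        p, r, f1 = classification_metrics(ConfusionCounts(tp=9, fp=1, fn=9, tn=0))
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(0.5)
        assert f1 == pytest.approx(2 * 0.9 * 0.5 / 1.4)

    def test_harmonic_mean_identity(self):
        p, r, f1 = classification_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert p == r == f1 == pytest.approx(0.75)

    def test_zero_over_zero_convention(self):
        with pytest.warns(RuntimeWarning):
            p, r, f1 = classification_metrics(ConfusionCounts(0, 0, 4, 6))
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_confusion_counts_partition(self, rng):
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        c = confusion_counts(y, pred)
        assert c.n == 50


class TestPRCurve:
    def test_perfect_ranking(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.8, 0.2, 0.1]
        assert pr_curve(y, s).auprc == pytest.approx(1.0)

    def test_single_positive_ranked_last(self):
        y = np.zeros(10, int)
        y[-1] = 1
        s = np.linspace(1.0, 0.1, 10)
        assert pr_curve(y, s).auprc == pytest.approx(0.1)

    def test_constant_scores_give_prevalence(self):
        y = np.array([1] * 3 + [0] * 7)
        assert pr_curve(y, np.full(10, 0.5)).auprc == pytest.approx(0.3)

    def test_recall_non_decreasing(self, rng):
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        curve = pr_curve(y, rng.uniform(0, 1, 40))
        assert np.all(np.diff(curve.recall) >= 0)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = np.round(rng.uniform(0, 1, n), 2)  # provoke ties
            assert pr_curve(y, s).auprc == pytest.approx(
                ap_bruteforce(y, s), abs=1e-12
            )

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(20):
            y = rng.integers(0, 2, 50)
            y[:2] = [0, 1]
            s = rng.uniform(0, 1, 50)
            assert pr_curve(y, s).auprc == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([1, 1, 1], [0.1, 0.2, 0.3])


class TestRepeatedStratifiedCV:
    def _features(self, n=60, n_pos=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, 5))
        y = np.zeros(n, int)
        y[:n_pos] = 1
        X[y == 1] += 1.5
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        df["label"] = y
        return df

    def test_report_has_one_row_per_fold(self):
        rep = repeated_stratified_cv(
            self._features(), "adaboost", folds=5, repeats=5, seed=3, rounds=5
        )
        assert len(rep.folds) == 25
        assert rep.means["auprc"] > 0.5

    def test_stratification_splits_minority_evenly(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 43 + [0] * 256)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        X = np.zeros((299, 1))
        for _, te in skf.split(X, y):
            assert np.sum(y[te]) in (8, 9)

    def test_same_seed_reproduces_report(self):
        f = self._features()
        a = repeated_stratified_cv(f, "adaboost", repeats=2, seed=5, rounds=5)
        b = repeated_stratified_cv(f, "adaboost", repeats=2, seed=5, rounds=5)
        pd.testing.assert_frame_equal(a.folds, b.folds)

    def test_minority_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            repeated_stratified_cv(
                self._features(n_pos=3), "adaboost", folds=5, seed=0
            )

    def test_training_fold_row_order_does_not_leak(self):
        """Held-out predictions depend on training content, not order."""
        from acrboost import boosting
        from sklearn.model_selection import StratifiedKFold

        f = self._features(seed=4)
        y = f["label"].to_numpy()
        X = f.drop(columns="label").to_numpy()
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=1)
        tr, te = next(iter(skf.split(X, y)))
        perm = np.random.default_rng(0).permutation(len(tr))
        m1 = boosting.fit_algorithm("adaboost", X[tr], y[tr], rounds=5, seed=2)
        m2 = boosting.fit_algorithm(
            "adaboost", X[tr][perm], y[tr][perm], rounds=5, seed=2
        )
        assert np.allclose(m1.predict_score(X[te]), m2.predict_score(X[te]))


class TestGridSearch:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (80, 4))
        y = (X[:, 0] * X[:, 1] > 0).astype(int)  # needs depth >= 2
        return X, y

    def test_single_point_grid_returned(self):
        X, y = self._data()
        assert grid_search(X, y, "adaboost", [{"depth": 2}], seed=0) == {"depth": 2}

    def test_duplicated_point_equivalent_to_deduplicated(self):
        X, y = self._data()
        grid = [{"depth": 1}, {"depth": 2}]
        assert grid_search(X, y, "adaboost", grid + grid, seed=1) == grid_search(
            X, y, "adaboost", grid, seed=1
        )

    def test_recovers_interaction_depth_above_chance(self):
        hits = 0
        for seed in range(6):
            X, y = self._data(seed)
            best = grid_search(
                X, y, "adaboost", [{"depth": 1}, {"depth": 2}], seed=seed
            )
            hits += best == {"depth": 2}
        assert hits >= 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 1)), np.array([0, 1, 0, 1]), "adaboost", [])
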