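"""Resamplers and boosting loops."""

import numpy as np
import pytest

from acrboost.boosting import (
    ALGORITHMS,
    Ensemble,
    ResampleError,
    ResamplePlan,
    cluster_undersample,
    cluster_undersample_indices,
    fit_adaboost,
    fit_algorithm,
    fit_cusboost,
    fit_rusboost,
    fit_smoteboost,
    predict_label,
    predict_score,
    random_undersample,
    smote_oversample,
)


class TestSMOTE:
    def test_two_points_interpolate_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        synth = smote_oversample(X, 20, k=1, seed=0)
        assert synth.shape == (20, 2)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0) & (synth <= 1))

    def test_zero_requested_rows(self):
        X = np.array([[0.0], [1.0]])
        assert smote_oversample(X, 0, k=1, seed=0).shape == (0, 1)

    def test_synthetic_rows_within_bounding_box(self, rng):
        X = rng.normal(0, 1, (15, 4))
        synth = smote_oversample(X, 100, k=5, seed=1)
        assert np.all(synth >= X.min(axis=0) - 1e-12)
        assert np.all(synth <= X.max(axis=0) + 1e-12)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(0, 1, (10, 3))
        a = smote_oversample(X, 25, k=3, seed=7)
        b = smote_oversample(X, 25, k=3, seed=7)
        assert np.array_equal(a, b)

    def test_preconditions(self):
        with pytest.raises(ResampleError):
            smote_oversample(np.array([[1.0]]), 5, k=1, seed=0)
        with pytest.raises(ResampleError):
            smote_oversample(np.array([[0.0], [1.0]]), 5, k=2, seed=0)


class TestRandomUndersample:
    def test_keep_all_is_identity_as_set(self, rng):
        X = rng.normal(0, 1, (8, 2))
        kept = random_undersample(X, 8, seed=0)
        assert np.array_equal(np.sort(kept, axis=0), np.sort(X, axis=0))

    def test_deterministic_singleton(self):
        X = np.array([[1.0], [2.0], [3.0]])
        a = random_undersample(X, 1, seed=5)
        b = random_undersample(X, 1, seed=5)
        assert np.array_equal(a, b)

    def test_repeated_draws_cover_all_rows(self):
        X = np.arange(12.0).reshape(-1, 1)
        seen = set()
        for s in range(1000):
            seen.update(random_undersample(X, 1, seed=s).ravel())
        assert seen == set(X.ravel())

    def test_overdraw_rejected(self):
        with pytest.raises(ResampleError):
            random_undersample(np.zeros((3, 1)), 4, seed=0)


class TestClusterUndersample:
    def test_proportional_allocation_over_separated_blobs(self, rng):
        big = rng.normal(0, 0.3, (80, 2))
        small = rng.normal(50, 0.3, (20, 2))
        X = np.vstack([big, small])
        idx = cluster_undersample_indices(X, n_clusters=2, n_keep=10, seed=0)
        n_from_big = int(np.sum(idx < 80))
        assert n_from_big == 8 and len(idx) - n_from_big == 2

    def test_keep_all(self, rng):
        X = rng.normal(0, 1, (12, 2))
        assert len(cluster_undersample(X, 3, 12, seed=1)) == 12

    def test_single_cluster_degenerates_to_uniform_subsample(self, rng):
        X = rng.normal(0, 1, (30, 2))
        kept = cluster_undersample(X, 1, 10, seed=2)
        assert kept.shape == (10, 2)
        # every kept row is an original row
        assert all(any(np.array_equal(r, x) for x in X) for r in kept)


def _separable_1d(n=30):
    X = np.linspace(0, 1, n).reshape(-1, 1)
    y = (X.ravel() > 0.5).astype(int)
    return X, y


def _xor_blobs(seed=0, n=40):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal([0, 0], 0.5, (n, 2)),
            rng.normal([3, 3], 0.5, (n, 2)),
            rng.normal([0, 3], 0.5, (n, 2)),
            rng.normal([3, 0], 0.5, (n, 2)),
        ]
    )
    y = np.array([1] * (2 * n) + [0] * (2 * n))
    return X, y


class TestAdaBoost:
    def test_separable_data_solved_in_one_round(self):
        X, y = _separable_1d()
        ens = fit_adaboost(X, y, rounds=10, depth=1, seed=0)
        assert len(ens) == 1  # eps = 0 ends boosting with that tree
        assert ens.train_error == 0.0

    def test_boosted_stumps_beat_any_single_stump_on_xor(self):
        X, y = _xor_blobs()
        ens = fit_adaboost(X, y, rounds=200, depth=1, seed=0, cost_sensitive=False)
        acc = np.mean(predict_label(ens, X) == y)
        single = fit_adaboost(X, y, rounds=1, depth=1, seed=0, cost_sensitive=False)
        single_acc = np.mean(predict_label(single, X) == y)
        assert acc > 0.75 > single_acc

    def test_matches_sklearn_adaboost_on_xor(self):
        """Independent cross-check of the AdaBoost.M1 loop."""
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        X, y = _xor_blobs()
        ours = fit_adaboost(X, y, rounds=200, depth=1, seed=0, cost_sensitive=False)
        ref = AdaBoostClassifier(
            DecisionTreeClassifier(max_depth=1), n_estimators=200, random_state=0
        ).fit(X, y)
        assert np.mean(predict_label(ours, X) == y) == pytest.approx(
            ref.score(X, y)
        )

    def test_exponential_loss_bound_holds(self, rng):
        for _ in range(10):
            X = rng.normal(0, 1, (60, 3))
            y = (X[:, 0] + rng.normal(0, 1, 60) > 0).astype(int)
            if len(set(y)) < 2:
                continue
            ens = fit_adaboost(X, y, rounds=20, depth=1, seed=1)
            assert ens.train_error <= ens.loss_bound + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_adaboost(np.zeros((5, 1)), np.ones(5, dtype=int), rounds=3)

    def test_bitwise_determinism(self, rng):
        X = rng.normal(0, 1, (50, 4))
        y = (X[:, 0] > 0).astype(int)
        s1 = predict_score(fit_adaboost(X, y, rounds=15, seed=9), X)
        s2 = predict_score(fit_adaboost(X, y, rounds=15, seed=9), X)
        assert np.array_equal(s1, s2)


class TestImbalancedBoosters:
    def test_balanced_data_parity_reduces_to_adaboost(self, rng):
        """With balanced classes and parity target the round resample is a
        no-op, so all three boosters coincide with plain AdaBoost."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (40, 3))
            y = np.array([0, 1] * 20)
            X[y == 1] += 0.8
            ada = fit_adaboost(X, y, rounds=10, seed=seed, cost_sensitive=False)
            for fit in (fit_smoteboost, fit_rusboost, fit_cusboost):
                ens = fit(X, y, rounds=10, seed=seed)
                assert ens.train_error == ada.train_error
                assert np.array_equal(
                    predict_score(ens, X), predict_score(ada, X)
                )

    def test_boosters_lift_minority_recall_over_plain_adaboost(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (300, 4)), rng.normal(0.8, 1, (30, 4))])
        y = np.array([0] * 300 + [1] * 30)
        plain = fit_adaboost(X, y, rounds=30, depth=2, seed=3, cost_sensitive=False)

        def recall(ens):
            pred = (predict_score(ens, X) >= 0.5).astype(int)
            return np.sum((pred == 1) & (y == 1)) / 30

        base = recall(plain)
        for fit in (fit_smoteboost, fit_rusboost, fit_cusboost):
            assert recall(fit(X, y, rounds=30, depth=2, seed=3)) > base

    def test_one_round_rusboost_is_rus_then_tree(self, rng):
        X = rng.normal(0, 1, (60, 2))
        y = np.array([0] * 50 + [1] * 10)
        X[y == 1] += 2
        ens = fit_rusboost(X, y, rounds=1, seed=4)
        assert len(ens) == 1


class TestScoring:
    def test_single_learner_probability_passthrough(self, rng):
        X = rng.normal(0, 1, (30, 2))
        y = (X[:, 0] > 0).astype(int)
        ens = fit_adaboost(X, y, rounds=1, depth=2, seed=0)
        assert len(ens) == 1
        tree, _ = ens.rounds[0]
        col = int(np.flatnonzero(tree.classes_ == 1)[0])
        assert np.allclose(predict_score(ens, X), tree.predict_proba(X)[:, col])

    def test_scores_bounded(self, rng):
        X = rng.normal(0, 1, (80, 3))
        y = (X[:, 0] + rng.normal(0, 0.5, 80) > 0).astype(int)
        s = predict_score(fit_adaboost(X, y, rounds=25, seed=2), X)
        assert np.all((s >= 0) & (s <= 1))

    def test_vote_weights_positive(self, rng):
        X = rng.normal(0, 1, (60, 3))
        y = (X[:, 1] > 0).astype(int)
        ens = fit_adaboost(X, y, rounds=20, seed=0)
        assert all(a > 0 for _, a in ens.rounds)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            predict_score(Ensemble(algorithm="adaboost"), np.zeros((2, 2)))


class TestAlgorithmRegistry:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_algorithm("gradboost", np.zeros((4, 1)), np.array([0, 1, 0, 1]))

    @pytest.mark.parametrize("name", ALGORITHMS)
    def test_all_nine_fit_and_score(self, name, rng):
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(1.5, 1, (10, 3))])
        y = np.array([0] * 40 + [1] * 10)
        model = fit_algorithm(name, X, y, rounds=5, depth=2, seed=0)
        s = model.predict_score(X)
        assert s.shape == (50,)
        assert np.all((s >= 0) & (s <= 1))
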