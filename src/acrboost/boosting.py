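"""Resamplers and boosting algorithms for imbalanced binary classification.

Implements the nine-algorithm comparison grid:

* cost-sensitive boosting: AdaBoost.M1 with class-cost initial weights,
  and a gradient-boosted-tree baseline (XGBoost) with a positive-class
  weight;
* one-shot resampling before boosting: SMOTE or random undersampling
  applied once to the training data, then AdaBoost / XGBoost;
* imbalanced-class boosting: SMOTEBoost, RUSBoost and CUSBoost, which
  re-balance the weighted training sample inside every boosting round
  while computing the round error, vote weight and weight update on the
  original (un-resampled) samples.

The weak learner is a depth-limited CART decision tree. Gradient-boosted
tree internals are delegated to the xgboost library behind the same
fit/score interface; the boosting loops and resamplers here are
implemented from first principles.

Labels are 0 (majority / normal) and 1 (minority / aggressive)
throughout. All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ResamplePlan",
    "Ensemble",
    "ResampleError",
    "smote_oversample",
    "random_undersample",
    "cluster_undersample",
    "fit_adaboost",
    "fit_smoteboost",
    "fit_rusboost",
    "fit_cusboost",
    "predict_score",
    "predict_label",
    "ALGORITHMS",
    "fit_algorithm",
]


class ResampleError(ValueError):
    pass


@dataclass(frozen=True)
class ResamplePlan:
    """How a boosting round (or a one-shot preprocessing step) re-balances.

    target_ratio is the minority:majority ratio after resampling
    (1 = full parity).
    """

    method: str = "smote"  # smote | rus | cus
    k_neighbors: int = 5
    n_clusters: int = 3
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")


@dataclass
class Ensemble:
    """A fitted boosted ensemble: weak trees with positive vote weights."""

    algorithm: str
    rounds: list = field(default_factory=list)  # [(tree, alpha)]
    train_error: float = float("nan")  # weighted 0/1 error under init dist
    loss_bound: float = float("nan")  # prod_t 2 sqrt(eps_t (1 - eps_t))

    def __len__(self) -> int:
        return len(self.rounds)


# ---------------------------------------------------------------- resamplers


def smote_oversample(
    minority_rows: np.ndarray, n_new: int, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Synthesise minority rows by interpolating to k-nearest neighbours.

    Each synthetic row is x + lam * (x_nn - x) with x a uniformly drawn
    minority row, x_nn one of its k nearest minority neighbours
    (Euclidean, excluding itself) and lam ~ Uniform(0, 1).
    """
    X = np.asarray(minority_rows, dtype=float)
    if len(X) < 2:
        raise ResampleError("SMOTE needs at least 2 minority rows")
    if k >= len(X):
        raise ResampleError(f"k={k} must be < minority count {len(X)}")
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return np.empty((0, X.shape[1]))
    rng = np.random.default_rng(seed)
    # pairwise distances; argsort row-wise, skip self at position 0
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, 1 : k + 1]
    base = rng.integers(0, len(X), size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    neigh = nn_idx[base, pick]
    return X[base] + lam[:, None] * (X[neigh] - X[base])


def random_undersample(
    majority_rows: np.ndarray, n_keep: int, seed: int = 0
) -> np.ndarray:
    """Uniform subsample of majority rows without replacement (indices via
    :func:`random_undersample_indices`)."""
    X = np.asarray(majority_rows)
    return X[random_undersample_indices(len(X), n_keep, seed)]


def random_undersample_indices(n: int, n_keep: int, seed: int = 0) -> np.ndarray:
    if not (0 < n_keep <= n):
        raise ResampleError(f"n_keep={n_keep} out of range (0, {n}]")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=n_keep, replace=False))


def cluster_undersample_indices(
    majority_rows: np.ndarray,
    n_clusters: int,
    n_keep: int,
    seed: int = 0,
    max_retries: int = 5,
) -> np.ndarray:
    """Cluster-proportional undersampling indices (the CUS step).

    K-means partitions the majority class; ``n_keep`` rows are allocated
    to clusters proportionally to their sizes (largest-remainder
    rounding) and drawn uniformly within each cluster, preserving the
    majority's modes instead of thinning them uniformly.
    """
    X = np.asarray(majority_rows, dtype=float)
    n = len(X)
    if n_clusters > n:
        raise ResampleError("n_clusters exceeds majority count")
    if not (0 < n_keep <= n):
        raise ResampleError(f"n_keep={n_keep} out of range (0, {n}]")
    for attempt in range(max_retries):
        km = KMeans(
            n_clusters=n_clusters, n_init=3, random_state=seed + attempt
        ).fit(X)
        sizes = np.bincount(km.labels_, minlength=n_clusters)
        if np.all(sizes > 0):
            break
    else:
        raise ResampleError("k-means produced an empty cluster repeatedly")

    # largest-remainder allocation of n_keep over cluster sizes
    quota = n_keep * sizes / n
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = n_keep - alloc.sum()
    for c in np.argsort(-remainder, kind="stable")[:short]:
        alloc[c] += 1
    alloc = np.minimum(alloc, sizes)
    # if capping created a shortfall, top up from clusters with room
    while alloc.sum() < n_keep:
        room = sizes - alloc
        c = int(np.argmax(room))
        alloc[c] += 1

    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in range(n_clusters):
        members = np.flatnonzero(km.labels_ == c)
        if alloc[c] > 0:
            keep.append(rng.choice(members, size=alloc[c], replace=False))
    return np.sort(np.concatenate(keep))


def cluster_undersample(
    majority_rows: np.ndarray,
    n_clusters: int,
    n_keep: int,
    seed: int = 0,
) -> np.ndarray:
    X = np.asarray(majority_rows)
    return X[cluster_undersample_indices(X, n_clusters, n_keep, seed)]


# ------------------------------------------------------------------ boosting

_EPS = 1e-10
_MAX_DISCARDS = 10  # consecutive eps >= 0.5 rounds tolerated when resampling


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    return X, y


def _initial_weights(y: np.ndarray, cost_sensitive: bool) -> np.ndarray:
    """Sample weights proportional to class costs, normalised to sum 1.

    Cost-sensitive mode uses inverse class frequency, so the minority
    class carries the imbalance ratio as its relative cost.
    """
    n = len(y)
    if not cost_sensitive:
        return np.full(n, 1.0 / n)
    w = np.where(y == 1, 1.0 / np.sum(y == 1), 1.0 / np.sum(y == 0))
    return w / w.sum()


def _round_seeds(seed: int, rounds: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(rounds)]


def _boost(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int,
    depth: int,
    seed: int,
    cost_sensitive: bool,
    algorithm: str,
    resample_round=None,
) -> Ensemble:
    """Shared AdaBoost.M1 loop.

    ``resample_round(X, y, w, rng_seed) -> (X_fit, y_fit, w_fit)`` builds
    the (possibly re-balanced) sample each weak learner is fitted on;
    the round error eps_t, vote weight alpha_t and the multiplicative
    weight update are always computed on the original samples.

    A round with eps_t >= 0.5 is discarded. Without round resampling the
    weak learner is deterministic, so boosting stops there; with round
    resampling the round is stochastic and a fresh resample is tried
    instead, up to ``_MAX_DISCARDS`` consecutive discards. eps_t = 0
    keeps the round (with a capped alpha) and stops.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    w = _initial_weights(y, cost_sensitive)
    w0 = w.copy()
    ens = Ensemble(algorithm=algorithm)
    seeds = _round_seeds(seed, rounds + _MAX_DISCARDS)
    bound = 1.0
    discards = 0
    t = -1
    while len(ens.rounds) < rounds:
        t += 1
        if t >= len(seeds):
            break
        if resample_round is None:
            X_fit, y_fit, w_fit = X, y, w
        else:
            X_fit, y_fit, w_fit = resample_round(X, y, w, seeds[t])
        tree = DecisionTreeClassifier(max_depth=depth, random_state=seeds[t])
        tree.fit(X_fit, y_fit, sample_weight=w_fit * len(w_fit))
        pred = tree.predict(X)
        miss = pred != y
        eps = float(np.sum(w[miss]))
        if eps >= 0.5:
            if resample_round is None:
                break
            discards += 1
            if discards > _MAX_DISCARDS:
                break
            continue
        discards = 0
        eps_c = min(max(eps, _EPS), 1.0 - _EPS)
        alpha = 0.5 * np.log((1.0 - eps_c) / eps_c)
        ens.rounds.append((tree, float(alpha)))
        bound *= 2.0 * np.sqrt(eps_c * (1.0 - eps_c))
        if eps <= _EPS:
            break
        w = w * np.exp(np.where(miss, alpha, -alpha))
        w = w / w.sum()
    if not ens.rounds:
        # every round was too weak; keep a single majority-vote stump
        tree = DecisionTreeClassifier(max_depth=1, random_state=seeds[0])
        tree.fit(X, y, sample_weight=w0 * len(w0))
        ens.rounds.append((tree, 1.0))
        bound = 1.0
    hard = predict_label(ens, X)
    ens.train_error = float(np.sum(w0[hard != y]))
    ens.loss_bound = float(bound)
    return ens


def fit_adaboost(
    X,
    y,
    rounds: int = 50,
    depth: int = 2,
    seed: int = 0,
    cost_sensitive: bool = True,
) -> Ensemble:
    """Cost-sensitive AdaBoost.M1 with depth-limited tree weak learners."""
    X, y = _check_xy(X, y)
    return _boost(X, y, rounds, depth, seed, cost_sensitive, "adaboost")


def _resample_smote(plan: ResamplePlan):
    def inner(X, y, w, rseed):
        min_idx = np.flatnonzero(y == 1)
        maj_idx = np.flatnonzero(y == 0)
        n_target = int(round(plan.target_ratio * len(maj_idx)))
        n_new = max(n_target - len(min_idx), 0)
        if n_new == 0 or len(min_idx) < 2:
            return X, y, w
        k = min(plan.k_neighbors, len(min_idx) - 1)
        synth = smote_oversample(X[min_idx], n_new, k=k, seed=rseed)
        w_synth = np.full(n_new, w[min_idx].mean())
        X_fit = np.vstack([X, synth])
        y_fit = np.concatenate([y, np.ones(n_new, dtype=int)])
        w_fit = np.concatenate([w, w_synth])
        return X_fit, y_fit, w_fit / w_fit.sum()

    return inner


def _resample_rus(plan: ResamplePlan):
    def inner(X, y, w, rseed):
        min_idx = np.flatnonzero(y == 1)
        maj_idx = np.flatnonzero(y == 0)
        n_keep = int(round(len(min_idx) / plan.target_ratio))
        if n_keep >= len(maj_idx):
            return X, y, w
        kept = maj_idx[random_undersample_indices(len(maj_idx), n_keep, rseed)]
        sel = np.sort(np.concatenate([min_idx, kept]))
        w_sel = w[sel]
        return X[sel], y[sel], w_sel / w_sel.sum()

    return inner


def _resample_cus(plan: ResamplePlan):
    def inner(X, y, w, rseed):
        min_idx = np.flatnonzero(y == 1)
        maj_idx = np.flatnonzero(y == 0)
        n_keep = int(round(len(min_idx) / plan.target_ratio))
        if n_keep >= len(maj_idx):
            return X, y, w
        k = min(plan.n_clusters, len(maj_idx))
        kept = maj_idx[
            cluster_undersample_indices(X[maj_idx], k, n_keep, seed=rseed)
        ]
        sel = np.sort(np.concatenate([min_idx, kept]))
        w_sel = w[sel]
        return X[sel], y[sel], w_sel / w_sel.sum()

    return inner


def fit_smoteboost(
    X, y, rounds: int = 50, plan: ResamplePlan | None = None,
    depth: int = 2, seed: int = 0,
) -> Ensemble:
    """AdaBoost with fresh SMOTE oversampling inside every round.

    Synthetic rows receive the mean weight of real minority rows for
    learner fitting and are discarded before the weight update.
    """
    X, y = _check_xy(X, y)
    plan = plan or ResamplePlan(method="smote")
    return _boost(
        X, y, rounds, depth, seed, False, "smoteboost", _resample_smote(plan)
    )


def fit_rusboost(
    X, y, rounds: int = 50, plan: ResamplePlan | None = None,
    depth: int = 2, seed: int = 0,
) -> Ensemble:
    """AdaBoost with fresh random undersampling inside every round."""
    X, y = _check_xy(X, y)
    plan = plan or ResamplePlan(method="rus")
    return _boost(
        X, y, rounds, depth, seed, False, "rusboost", _resample_rus(plan)
    )


def fit_cusboost(
    X, y, rounds: int = 50, plan: ResamplePlan | None = None,
    depth: int = 2, seed: int = 0,
) -> Ensemble:
    """AdaBoost with cluster-proportional undersampling inside every round."""
    X, y = _check_xy(X, y)
    plan = plan or ResamplePlan(method="cus")
    return _boost(
        X, y, rounds, depth, seed, False, "cusboost", _resample_cus(plan)
    )


def predict_score(ensemble: Ensemble, X) -> np.ndarray:
    """Vote-weighted mean of weak-learner class-1 probabilities, in [0, 1]."""
    if not ensemble.rounds:
        raise ValueError("cannot score an empty ensemble")
    X = np.asarray(X, dtype=float)
    alphas = np.array([a for _, a in ensemble.rounds])
    probs = np.stack(
        [_tree_proba1(tree, X) for tree, _ in ensemble.rounds], axis=1
    )
    return probs @ (alphas / alphas.sum())


def predict_label(ensemble: Ensemble, X) -> np.ndarray:
    """Classic alpha-weighted majority vote (hard 0/1 labels).

    This is the prediction the exponential-loss bound
    prod_t 2 sqrt(eps_t (1 - eps_t)) applies to; ``predict_score``'s soft
    probability average is used for ranking metrics instead.
    """
    if not ensemble.rounds:
        raise ValueError("cannot score an empty ensemble")
    X = np.asarray(X, dtype=float)
    alphas = np.array([a for _, a in ensemble.rounds])
    votes = np.stack(
        [2.0 * tree.predict(X) - 1.0 for tree, _ in ensemble.rounds], axis=1
    )
    return (votes @ alphas >= 0.0).astype(int)


def _tree_proba1(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    proba = tree.predict_proba(X)
    if proba.shape[1] == 1:  # degenerate single-class tree
        return np.full(len(X), float(tree.classes_[0]))
    col = int(np.flatnonzero(tree.classes_ == 1)[0])
    return proba[:, col]


# ------------------------------------------------------- algorithm registry

ALGORITHMS = (
    "adaboost",
    "xgboost",
    "smote+adaboost",
    "smote+xgboost",
    "rus+adaboost",
    "rus+xgboost",
    "smoteboost",
    "rusboost",
    "cusboost",
)


class _XGBModel:
    """Thin adapter over xgboost with the same predict_score surface."""

    def __init__(self, booster):
        self._booster = booster

    def predict_score(self, X):
        return self._booster.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _fit_xgboost(X, y, rounds, depth, seed, cost_sensitive):
    from xgboost import XGBClassifier

    pos = int(np.sum(y == 1))
    neg = int(np.sum(y == 0))
    clf = XGBClassifier(
        n_estimators=rounds,
        max_depth=depth,
        learning_rate=0.3,
        scale_pos_weight=(neg / pos if cost_sensitive and pos else 1.0),
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        eval_metric="logloss",
    )
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return _XGBModel(clf)


def _one_shot_resample(X, y, plan: ResamplePlan, seed: int):
    """Apply SMOTE or RUS once to a training set (preprocessing baselines)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    min_idx = np.flatnonzero(y == 1)
    maj_idx = np.flatnonzero(y == 0)
    if plan.method == "smote":
        n_target = int(round(plan.target_ratio * len(maj_idx)))
        n_new = max(n_target - len(min_idx), 0)
        if n_new == 0 or len(min_idx) < 2:
            return X, y
        k = min(plan.k_neighbors, len(min_idx) - 1)
        synth = smote_oversample(X[min_idx], n_new, k=k, seed=seed)
        return (
            np.vstack([X, synth]),
            np.concatenate([y, np.ones(n_new, dtype=int)]),
        )
    if plan.method == "rus":
        n_keep = int(round(len(min_idx) / plan.target_ratio))
        if n_keep >= len(maj_idx):
            return X, y
        kept = maj_idx[random_undersample_indices(len(maj_idx), n_keep, seed)]
        sel = np.sort(np.concatenate([min_idx, kept]))
        return X[sel], y[sel]
    raise ValueError(f"unknown one-shot resample method {plan.method!r}")


class _EnsembleModel:
    def __init__(self, ensemble: Ensemble):
        self.ensemble = ensemble

    def predict_score(self, X):
        return predict_score(self.ensemble, X)


def fit_algorithm(
    name: str,
    X,
    y,
    rounds: int = 50,
    depth: int = 2,
    seed: int = 0,
    plan: ResamplePlan | None = None,
):
    """Fit any of the nine benchmark algorithms; returns an object with
    ``predict_score(X) -> scores in [0, 1]``."""
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if name == "adaboost":
        return _EnsembleModel(fit_adaboost(X, y, rounds, depth, seed))
    if name == "xgboost":
        return _fit_xgboost(X, y, rounds, depth, seed, cost_sensitive=True)
    if name == "smoteboost":
        return _EnsembleModel(
            fit_smoteboost(X, y, rounds, plan or ResamplePlan("smote"), depth, seed)
        )
    if name == "rusboost":
        return _EnsembleModel(
            fit_rusboost(X, y, rounds, plan or ResamplePlan("rus"), depth, seed)
        )
    if name == "cusboost":
        return _EnsembleModel(
            fit_cusboost(X, y, rounds, plan or ResamplePlan("cus"), depth, seed)
        )
    method, base = name.split("+")
    Xr, yr = _one_shot_resample(X, y, plan or ResamplePlan(method), seed)
    if base == "adaboost":
        return _EnsembleModel(
            fit_adaboost(Xr, yr, rounds, depth, seed, cost_sensitive=False)
        )
    return _fit_xgboost(Xr, yr, rounds, depth, seed, cost_sensitive=False)
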