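"""Classifier evaluation under class imbalance.

Precision, recall and F1 at a fixed 0.5 score threshold; precision-recall
curves with step-wise average precision (AUPRC); repeated stratified
k-fold cross-validation; exhaustive grid search confined to training
folds. AUPRC is preferred over ROC area here because the aggressive class
is a small minority and ROC curves are insensitive to false positives in
that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import boosting

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "EvalReport",
    "classification_metrics",
    "confusion_counts",
    "pr_curve",
    "repeated_stratified_cv",
    "grid_search",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PRCurve:
    """Recall/precision points swept over descending score thresholds."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auprc: float


@dataclass
class EvalReport:
    """Per-fold metrics of a repeated stratified CV experiment."""

    folds: pd.DataFrame  # repeat, fold, precision, recall, f1, auprc
    algorithm: str
    n_folds: int
    n_repeats: int

    @property
    def means(self) -> pd.Series:
        return self.folds[["precision", "recall", "f1", "auprc"]].mean()


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 defined as 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); any 0/0 is defined as 0 with a warning."""
    precision = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "f1")
    return precision, recall, f1


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def pr_curve(labels, scores) -> PRCurve:
    """Precision-recall curve and step-wise average precision.

    Samples are sorted by descending score with ties grouped (one curve
    point per distinct score); AUPRC = sum_i (R_i - R_{i-1}) * P_i, i.e.
    average precision without the optimistic linear PR interpolation.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("PR curve needs both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # group ties: indices where a threshold block ends
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    block_ends = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp_cum = np.cumsum(y_sorted == 1)[block_ends]
    fp_cum = np.cumsum(y_sorted == 0)[block_ends]
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    auprc = float(np.sum((recall - prev_recall) * precision))
    return PRCurve(
        recall=recall,
        precision=precision,
        thresholds=s_sorted[block_ends],
        auprc=auprc,
    )


def grid_search(
    X_train,
    y_train,
    algorithm: str,
    grid: list[dict],
    inner_folds: int = 3,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search by inner stratified CV, maximising mean AUPRC.

    Ties break toward the smaller model: fewer boosting rounds, then
    shallower trees, then grid order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    # deduplicate, preserving order
    seen, points = set(), []
    for g in grid:
        key = tuple(sorted(g.items()))
        if key not in seen:
            seen.add(key)
            points.append(g)
    if len(points) == 1:
        return points[0]

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed % (2**31))
    results = []
    for g in points:
        aucs = []
        for k, (tr, te) in enumerate(skf.split(X_train, y_train)):
            model = boosting.fit_algorithm(
                algorithm, X_train[tr], y_train[tr], seed=seed + k, **g
            )
            scores = model.predict_score(X_train[te])
            aucs.append(pr_curve(y_train[te], scores).auprc)
        results.append((float(np.mean(aucs)), g))
    best_auc = max(r[0] for r in results)
    tied = [g for auc, g in results if auc >= best_auc - 1e-12]
    tied.sort(key=lambda g: (g.get("rounds", 0), g.get("depth", 0)))
    return tied[0]


def repeated_stratified_cv(
    features: pd.DataFrame,
    algorithm: str,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    grid: list[dict] | None = None,
    inner_folds: int = 3,
    **fit_kwargs,
) -> EvalReport:
    """Repeated stratified k-fold CV of one algorithm.

    ``features`` is the labeled matrix from
    :func:`acrboost.spectral_features.build_feature_matrix` (column
    ``label`` plus feature columns). Resampling and any grid search are
    confined to the training folds of each split; held-out metrics use
    the 0.5 score threshold plus the fold PR curve.
    """
    y = features["label"].to_numpy(dtype=int)
    X = features.drop(columns="label").to_numpy(dtype=float)
    if int(np.sum(y == 1)) < folds:
        raise ValueError("minority count smaller than fold count")
    rows = []
    for rep in range(repeats):
        rep_seed = (seed + 1000003 * rep) % (2**31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            params = dict(fit_kwargs)
            if grid:
                params.update(
                    grid_search(
                        X[tr], y[tr], algorithm, grid, inner_folds, seed=rep_seed + fold
                    )
                )
            model = boosting.fit_algorithm(
                algorithm, X[tr], y[tr], seed=rep_seed + fold, **params
            )
            scores = model.predict_score(X[te])
            pred = (scores >= 0.5).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p, r, f1 = classification_metrics(confusion_counts(y[te], pred))
            auprc = pr_curve(y[te], scores).auprc
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "precision": p,
                    "recall": r,
                    "f1": f1,
                    "auprc": auprc,
                }
            )
    return EvalReport(
        folds=pd.DataFrame(rows), algorithm=algorithm, n_folds=folds, n_repeats=repeats
    )
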