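"""Turning per-driver ACR values into binary aggressiveness labels.

Three anomaly-detection rules produce the ACR threshold:

* exact two-cluster 1-D k-means (split the sorted values at the point
  minimising the within-cluster sum of squares; the threshold is the
  midpoint of the inter-cluster gap),
* the interquartile-range outlier rule, threshold = Q3 + 1.5 * IQR,
* a plain percentile (default the 94th).

A driver is labeled aggressive iff its ACR strictly exceeds the
threshold. The module also computes the leader–follower ACR correlation
used to argue that a follower's crash risk is its own doing rather than
inherited from the vehicle ahead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdResult",
    "LabeledDriver",
    "kmeans_threshold",
    "iqr_threshold",
    "percentile_threshold",
    "label_drivers",
    "leader_follower_correlation",
]


@dataclass(frozen=True)
class ThresholdResult:
    method: str  # kmeans | iqr | percentile
    threshold: float  # ACR units (s)
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LabeledDriver:
    driver_id: int
    acr: float
    label: str  # "aggressive" | "normal"
    truth: str | None = None


def _as_array(acr_values) -> np.ndarray:
    x = np.asarray(list(acr_values), dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("ACR values must be finite")
    return x


def kmeans_threshold(acr_values: Iterable[float]) -> ThresholdResult:
    """Exact optimal 2-cluster 1-D k-means split.

    Optimal 1-D clusters are contiguous in sorted order, so scanning the
    n-1 split points of the sorted values finds the global minimiser of
    the within-cluster sum of squares — no iterative heuristic, no seed.
    """
    x = np.sort(_as_array(acr_values))
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct values for a 2-cluster split")
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # within-SS of x[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    best_k, best_e = None, np.inf
    for k in range(1, n):  # low cluster = x[:k]
        e = sse(0, k) + sse(k, n)
        if e < best_e - 1e-15:
            best_e, best_k = e, k
    lo, hi = x[:best_k], x[best_k:]
    thr = 0.5 * (lo[-1] + hi[0])
    return ThresholdResult(
        "kmeans",
        float(thr),
        {
            "mu_low": float(lo.mean()),
            "mu_high": float(hi.mean()),
            "within_ss": float(best_e),
            "n_low": int(best_k),
        },
    )


def iqr_threshold(acr_values: Iterable[float]) -> ThresholdResult:
    """Outlier rule Q3 + 1.5*IQR with linear-interpolation (type-7) quantiles."""
    x = _as_array(acr_values)
    if len(x) < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # numpy default = type 7
    iqr = q3 - q1
    return ThresholdResult(
        "iqr",
        float(q3 + 1.5 * iqr),
        {"q1": float(q1), "q3": float(q3), "iqr": float(iqr)},
    )


def percentile_threshold(
    acr_values: Iterable[float], x_percent: float = 94.0
) -> ThresholdResult:
    """Xth percentile of the ACR sample; declares ~(100-X)% aggressive."""
    if not (0.0 < x_percent < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    x = _as_array(acr_values)
    thr = np.percentile(x, x_percent)  # same type-7 convention
    return ThresholdResult("percentile", float(thr), {"x": float(x_percent)})


def label_drivers(
    acr_table: pd.DataFrame,
    threshold: float | ThresholdResult,
    truth: pd.DataFrame | None = None,
) -> tuple[list[LabeledDriver], dict]:
    """Label drivers aggressive iff acr > threshold (strict).

    ``acr_table`` needs columns ``follower_id`` (or ``driver_id``) and
    ``acr``; optional ``truth`` maps driver_id -> is_aggressive. Returns
    the labels plus summary diagnostics (minority fraction, imbalance
    ratio).
    """
    thr = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    idcol = "driver_id" if "driver_id" in acr_table.columns else "follower_id"
    truth_map = {}
    if truth is not None:
        truth_map = {
            int(r.driver_id): ("aggressive" if r.is_aggressive else "normal")
            for r in truth.itertuples(index=False)
        }
    labeled = [
        LabeledDriver(
            driver_id=int(row[idcol]),
            acr=float(row["acr"]),
            label="aggressive" if row["acr"] > thr else "normal",
            truth=truth_map.get(int(row[idcol])),
        )
        for _, row in acr_table.iterrows()
    ]
    n = len(labeled)
    n_aggr = sum(ld.label == "aggressive" for ld in labeled)
    summary = {
        "threshold": thr,
        "n_drivers": n,
        "n_aggressive": n_aggr,
        "minority_fraction": n_aggr / n if n else float("nan"),
        "imbalance_ratio": (n - n_aggr) / n_aggr if n_aggr else float("inf"),
    }
    return labeled, summary


def leader_follower_correlation(
    labeled: Sequence[LabeledDriver], episodes
) -> tuple[float, int]:
    """Pearson correlation of (leader ACR, follower ACR) over pairs whose
    leader is itself a labeled follower. Near-zero correlation supports
    reading ACR as a property of the driver, not of local traffic."""
    acr_by_id = {ld.driver_id: ld.acr for ld in labeled}
    pairs = [
        (acr_by_id[ep.leader_id], acr_by_id[ep.follower_id])
        for ep in episodes
        if ep.leader_id in acr_by_id and ep.follower_id in acr_by_id
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 qualifying pairs, got {len(pairs)}")
    arr = np.asarray(pairs)
    r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
    return float(r), len(pairs)
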