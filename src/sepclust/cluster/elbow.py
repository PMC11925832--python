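"""Within-cluster sum of squares and automated elbow selection of k.

The elbow detector runs an algorithm over a range of cluster counts,
min-max-normalizes both axes of the (k, WCSS) curve, and picks the k whose
curve point lies farthest (perpendicular distance) from the chord joining
the first and last points — the point where the rate of decrease in WCSS
sharply falls.  Ties resolve to the smallest k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


def wcss(X, labels) -> float:
    """Sum over clusters of squared Euclidean distances to the centroid."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels):
        sel = labels == c
        if not sel.any():
            raise ValueError(f"cluster {c} has no members")
        centroid = X[sel].mean(0)
        total += float(((X[sel] - centroid) ** 2).sum())
    return total


@dataclass
class ElbowCurve:
    k_values: np.ndarray
    criterion: np.ndarray  # WCSS per k
    k_opt: int

    def as_records(self) -> list[dict]:
        return [{"k": int(k), "wcss": float(w)}
                for k, w in zip(self.k_values, self.criterion)]


def elbow_point(k_values: Sequence[int], criterion: Sequence[float]) -> int:
    """Max-perpendicular-distance knee of a (k, criterion) curve."""
    k_values = np.asarray(k_values, dtype=float)
    criterion = np.asarray(criterion, dtype=float)
    if len(k_values) < 3:
        raise ValueError("elbow detection needs at least 3 k values")
    if np.any(np.diff(k_values) <= 0):
        raise ValueError("k_values must be strictly increasing")
    if np.any(np.diff(criterion) > 0):
        logger.info("elbow curve is not monotone non-increasing")

    def norm(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    x, y = norm(k_values), norm(criterion)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        warnings.warn("degenerate elbow curve; selecting smallest k")
        return int(k_values[0])
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / chord
    if np.allclose(dist, 0.0):
        warnings.warn("exactly linear elbow curve; selecting smallest k")
        return int(k_values[0])
    return int(k_values[int(np.argmax(dist))])  # argmax returns smallest tie index


def find_elbow(X, algorithm: str = "kmeans", k_range: Iterable[int] = range(2, 121),
               params: dict | None = None, seed: int = 0) -> ElbowCurve:
    """Compute WCSS across k and select the elbow.

    One seed stream per (algorithm, k): each k uses ``seed + k`` so reruns
    are reproducible and k values do not share initialization accidents.
    """
    from .algorithms import run_algorithm

    X = np.asarray(X, dtype=float)
    ks = np.array(sorted(set(int(k) for k in k_range)))
    if ks[-1] >= X.shape[0]:
        raise ValueError("k_max must be < n")
    crit = np.empty(len(ks))
    for i, k in enumerate(ks):
        res = run_algorithm(algorithm, X, int(k), params, seed=seed + int(k))
        crit[i] = res.wcss
    return ElbowCurve(ks, crit, elbow_point(ks, crit))
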