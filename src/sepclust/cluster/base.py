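"""Shared clustering result container and small helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClusteringResult:
    """Uniform output of every algorithm in the bench.

    ``labels`` are 1-based cluster ids; ``weights`` is the per-feature
    weight vector (uniform except for RSKC); the trimmed sets are empty for
    non-robust algorithms.  ``objective`` is the weighted between-cluster
    criterion and ``wcss`` the plain within-cluster sum of squares.
    """

    labels: np.ndarray
    k: int
    algorithm: str
    weights: np.ndarray
    trimmed_weighted: frozenset = frozenset()
    trimmed_unweighted: frozenset = frozenset()
    objective: float = 0.0
    wcss: float = 0.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def _ensure_nonempty_labels(X: np.ndarray, labels: np.ndarray, k: int,
                            centers: np.ndarray | None = None) -> np.ndarray:
    """Guarantee exactly k non-empty clusters (0-based labels in, out).

    Any empty cluster is re-seeded with the case farthest from its current
    center (largest distance to the centroid of its assigned cluster),
    drawn from a cluster with more than one member.
    """
    labels = labels.copy()
    n = X.shape[0]
    if k > n:
        raise ValueError("cannot form more clusters than cases")
    for c in range(k):
        if (labels == c).any():
            continue
        counts = np.bincount(labels, minlength=k)
        cents = np.vstack([X[labels == j].mean(0) if counts[j] else np.zeros(X.shape[1])
                           for j in range(k)])
        d = ((X - cents[labels]) ** 2).sum(1)
        d[counts[labels] <= 1] = -np.inf  # do not empty another cluster
        far = int(np.argmax(d))
        labels[far] = c
    return labels
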