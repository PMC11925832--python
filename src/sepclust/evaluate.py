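"""Internal cluster validity, rank aggregation, and subsampling stability.

Five internal metrics compare algorithms without external labels:
silhouette (consistency, higher better), Davies-Bouldin (separation, lower
better), Calinski-Harabasz (dispersion ratio, higher better), Shannon
diversity of cluster sizes (balance, higher better) and the Gini index of
cluster sizes (inequality, lower better).  Algorithms are ranked per metric
(average ranks on ties) and ordered by rank sum.

Stability follows the subsampling protocol: B random subsamples of a
fraction of the data, R clustering runs per subsample with distinct seeds,
agreement within a subsample summarized as mean pairwise ARI/NMI, and the
coefficient of variation of agreement across subsamples as the stability
score (lower = more stable).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .cluster import run_algorithm

METRIC_DIRECTIONS = {
    # True = higher is better
    "silhouette": True,
    "davies_bouldin": False,
    "calinski_harabasz": True,
    "shannon": True,
    "gini": False,
}


def silhouette_mean(X, labels) -> float:
    """Mean silhouette coefficient s(i) = (b_i - a_i)/max(a_i, b_i)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(X, dtype=float), labels))


def davies_bouldin(X, labels) -> float:
    """DB = mean over clusters of max_j (S_i + S_j)/M_ij."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    cents = np.vstack([X[labels == c].mean(0) for c in ids])
    for i, j in itertools.combinations(range(len(ids)), 2):
        if np.allclose(cents[i], cents[j]):
            raise ZeroDivisionError(
                f"identical centroids for clusters {ids[i]} and {ids[j]}")
    return float(davies_bouldin_score(X, labels))


def calinski_harabasz(X, labels) -> float:
    """CH = [B/(k-1)] / [W/(n-k)]; +inf sentinel when W = 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    n = len(labels)
    if not 2 <= k <= n - 1:
        raise ValueError("Calinski-Harabasz requires 2 <= k <= n-1")
    W = sum(float(((X[labels == c] - X[labels == c].mean(0)) ** 2).sum())
            for c in np.unique(labels))
    if W == 0:
        warnings.warn("zero within-cluster dispersion; CH is infinite")
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


def shannon_diversity(cluster_sizes) -> float:
    """H = -sum p_c ln p_c over cluster size proportions."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    p = sizes / sizes.sum()
    return float(-(p * np.log(p)).sum())


def gini_index(cluster_sizes) -> float:
    """Mean absolute difference Gini: sum_ij |n_i - n_j| / (2 k^2 nbar)."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    k = len(sizes)
    nbar = sizes.mean()
    return float(np.abs(sizes[:, None] - sizes[None, :]).sum() / (2 * k * k * nbar))


def all_metrics(X, labels) -> dict[str, float]:
    sizes = np.bincount(np.asarray(labels))
    sizes = sizes[sizes > 0]
    return {
        "silhouette": silhouette_mean(X, labels),
        "davies_bouldin": davies_bouldin(X, labels),
        "calinski_harabasz": calinski_harabasz(X, labels),
        "shannon": shannon_diversity(sizes),
        "gini": gini_index(sizes),
    }


def rank_algorithms(metric_values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Direction-aware per-metric ranks, rank sums and the final ordering.

    ``metric_values`` maps algorithm -> {metric: value} with all five
    metrics present.  Ties within a metric get average ranks; equal rank
    sums are flagged tied and broken alphabetically in ``final_rank``.
    """
    algos = sorted(metric_values)
    for a in algos:
        missing = set(METRIC_DIRECTIONS) - set(metric_values[a])
        if missing:
            raise ValueError(f"algorithm {a!r} missing metrics: {sorted(missing)}")
    df = pd.DataFrame({a: metric_values[a] for a in algos}).T[list(METRIC_DIRECTIONS)]
    for metric, higher_better in METRIC_DIRECTIONS.items():
        v = df[metric].to_numpy(dtype=float)
        df[f"rank_{metric}"] = rankdata(-v if higher_better else v, method="average")
    rank_cols = [f"rank_{m}" for m in METRIC_DIRECTIONS]
    df["rank_sum"] = df[rank_cols].sum(axis=1)
    order = df.sort_values(["rank_sum"], kind="stable").index  # index already alphabetical
    df["final_rank"] = pd.Series(range(1, len(algos) + 1), index=order)
    df["tied"] = df["rank_sum"].duplicated(keep=False)
    return df


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model ARI from the pair contingency table."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("ARI requires at least 2 items")
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(labels_a, labels_b,
                                  average: str = "geometric") -> float:
    """NMI = I(U,V) / mean(H(U), H(V)); geometric mean by default.

    Two trivial (single-cluster) partitions give 1 by the 0/0 convention.
    """
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(a, b, average_method=average))


@dataclass
class StabilityReport:
    algorithm: str
    ari_mean: float
    ari_sd: float
    ari_cv: float
    nmi_mean: float
    nmi_sd: float
    nmi_cv: float
    B: int
    frac: float
    R: int


def stability_assess(X, algorithm, k: int, B: int = 50, frac: float = 0.8,
                     R: int = 20, pair_budget: int = 200, params: dict | None = None,
                     seed: int = 0) -> StabilityReport:
    """Subsampling stability of one algorithm at a fixed k.

    For each of B subsamples (``frac`` of rows, without replacement) the
    algorithm runs R times with distinct seeds; agreement is the mean
    pairwise ARI (and NMI) over at most ``pair_budget`` random run pairs.
    ``algorithm`` may be a registry name or a callable
    ``(X, k, seed) -> labels``.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = int(np.ceil(frac * n))
    if m <= k:
        raise ValueError("subsample size must exceed k")
    if R < 2:
        raise ValueError("R must be >= 2")
    rng = np.random.default_rng(seed)
    name = algorithm if isinstance(algorithm, str) else getattr(
        algorithm, "__name__", "callable")

    def _run(Xs, run_seed) -> np.ndarray:
        if isinstance(algorithm, str):
            return run_algorithm(algorithm, Xs, k, params, seed=run_seed).labels
        return np.asarray(algorithm(Xs, k, run_seed))

    all_pairs = list(itertools.combinations(range(R), 2))
    ari_vals = np.empty(B)
    nmi_vals = np.empty(B)
    for b in range(B):
        idx = rng.choice(n, size=m, replace=False)
        Xs = X[idx]
        runs = [_run(Xs, int(rng.integers(2**31 - 1))) for _ in range(R)]
        if len(all_pairs) > pair_budget:
            sel = rng.choice(len(all_pairs), size=pair_budget, replace=False)
            pairs = [all_pairs[i] for i in sel]
        else:
            pairs = all_pairs
        ari_vals[b] = np.mean([adjusted_rand_index(runs[i], runs[j]) for i, j in pairs])
        nmi_vals[b] = np.mean([normalized_mutual_information(runs[i], runs[j])
                               for i, j in pairs])

    def _cv(v):
        mu = v.mean()
        return float(v.std(ddof=1) / mu) if mu > 0 else float("nan")

    return StabilityReport(
        algorithm=name,
        ari_mean=float(ari_vals.mean()), ari_sd=float(ari_vals.std(ddof=1)),
        ari_cv=_cv(ari_vals),
        nmi_mean=float(nmi_vals.mean()), nmi_sd=float(nmi_vals.std(ddof=1)),
        nmi_cv=_cv(nmi_vals), B=B, frac=frac, R=R,
    )
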