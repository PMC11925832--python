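"""Robust and Sparse K-means clustering (RSKC), implemented from scratch.

RSKC augments K-means with two devices: *trimming* (a fraction alpha of the
cases farthest from their centers is excluded from center updates, giving
resilience to outliers) and *sparse feature weights* (an L1-bounded,
L2-normalized weight vector concentrates the clustering criterion on
informative features).  The algorithm alternates:

1. trimmed K-means under the current weights, yielding the weighted-trimmed
   set O_W (the ceil(alpha*n) cases farthest in weighted distance);
2. recomputing centers in *unweighted* space on the untrimmed cases and
   flagging O_E, the ceil(alpha*n) cases farthest in unweighted distance;
3. a weight update on cases outside O_W and O_E: per-feature
   between-cluster sums of squares b_j are soft-thresholded, w =
   S(b, delta) / ||S(b, delta)||_2 with the smallest delta >= 0 making
   ||w||_1 <= s (found by bisection; delta = 0 when already feasible).

Iteration stops when the weight vector moves less than ``tol``.  Final
labels assign every case — including trimmed ones — to its nearest weighted
center.  The best of ``n_init`` k-means++ restarts by the weighted
between-cluster objective is returned.

When the L1 bound sits at its maximum (s >= sqrt(p)) the sparsity device is
inactive by convention: weights stay uniform at 1/sqrt(p) and the procedure
reduces exactly to (trimmed) Lloyd K-means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base import ClusteringResult, _ensure_nonempty_labels


@dataclass
class RskcParams:
    alpha: float = 0.1        # trim fraction
    s: float | None = None    # L1 bound in [1, sqrt(p)]; None -> sqrt(p)
    n_init: int = 10
    max_iter: int = 50
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 0.5:
            raise ValueError("alpha must lie in [0, 0.5)")
        if self.s is not None and self.s < 1:
            raise ValueError("s must be >= 1")


def _weighted_sq_dist(X: np.ndarray, centers: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(n, k) matrix of weighted squared distances sum_j w_j (x_j - c_j)^2."""
    Xw = X * np.sqrt(w)
    Cw = centers * np.sqrt(w)
    d = ((Xw ** 2).sum(1)[:, None] - 2 * Xw @ Cw.T + (Cw ** 2).sum(1)[None, :])
    return np.maximum(d, 0.0)


def _kmeanspp(X: np.ndarray, k: int, w: np.ndarray, rng: np.random.Generator,
              n_trim: int = 0) -> np.ndarray:
    """k-means++ seeding on weighted distances.

    Trim-aware: the ``n_trim`` currently-farthest points are excluded from
    seed sampling, so gross outliers (which trimming will discard anyway)
    cannot become initial centers.
    """
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _weighted_sq_dist(X, centers[:1], w).ravel()
    for c in range(1, k):
        probs = d2.copy()
        if n_trim > 0:
            probs[np.argpartition(d2, n - n_trim)[n - n_trim:]] = 0.0
        total = probs.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=probs / total)
        centers[c] = X[idx]
        d2 = np.minimum(d2, _weighted_sq_dist(X, centers[c:c + 1], w).ravel())
    return centers


def _trimmed_kmeans(X, k, w, n_trim, rng, centers, max_iter=100):
    """Lloyd iterations under weights, excluding the n_trim farthest cases
    from center updates.  Returns labels, centers, trimmed index set."""
    n = X.shape[0]
    labels = np.full(n, -1)
    for _ in range(max_iter):
        D = _weighted_sq_dist(X, centers, w)
        new_labels = D.argmin(1)
        dmin = D[np.arange(n), new_labels]
        if n_trim > 0:
            trimmed = np.argpartition(dmin, n - n_trim)[n - n_trim:]
        else:
            trimmed = np.empty(0, dtype=int)
        keep = np.ones(n, dtype=bool)
        keep[trimmed] = False
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            sel = keep & (labels == c)
            if sel.any():
                centers[c] = X[sel].mean(0)
            else:  # empty cluster: re-seed with the farthest untrimmed case
                far = np.argmax(np.where(keep, dmin, -np.inf))
                centers[c] = X[far]
                labels[far] = c
                dmin[far] = 0.0
    D = _weighted_sq_dist(X, centers, w)
    labels = D.argmin(1)
    dmin = D[np.arange(n), labels]
    if n_trim > 0:
        trimmed = np.argpartition(dmin, n - n_trim)[n - n_trim:]
    else:
        trimmed = np.empty(0, dtype=int)
    return labels, centers, set(int(i) for i in trimmed)


def _bcss_per_feature(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature between-cluster sum of squares on the given rows."""
    grand = X.mean(0)
    b = np.zeros(X.shape[1])
    for c in np.unique(labels):
        sel = labels == c
        b += sel.sum() * (X[sel].mean(0) - grand) ** 2
    return b


def _soft_threshold_weights(b: np.ndarray, s: float) -> np.ndarray:
    """w = S(b, delta)/||S(b, delta)||_2 with smallest delta giving ||w||_1 <= s."""
    b = np.maximum(b, 0.0)
    if b.max() == 0:
        p = b.size
        return np.full(p, 1.0 / math.sqrt(p))

    def l1_of(delta: float) -> float:
        v = np.maximum(b - delta, 0.0)
        norm = np.linalg.norm(v)
        return v.sum() / norm if norm > 0 else 0.0

    if l1_of(0.0) <= s + 1e-10:
        v = b
    else:
        lo, hi = 0.0, float(b.max())
        for _ in range(80):
            mid = (lo + hi) / 2
            if l1_of(mid) > s:
                lo = mid
            else:
                hi = mid
        v = np.maximum(b - hi, 0.0)
    return v / np.linalg.norm(v)


def rskc(X, k: int, params: RskcParams = RskcParams(),
         init_centers: np.ndarray | None = None) -> ClusteringResult:
    """Run RSKC; best of ``n_init`` restarts by the weighted objective.

    ``init_centers`` (k x p) bypasses k-means++ seeding with a single fixed
    start — useful for comparing against a reference K-means run from the
    same initialization.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    n_trim = math.ceil(params.alpha * n)
    if k >= n - n_trim:
        raise ValueError("k must be < n - ceil(alpha*n)")
    s = math.sqrt(p) if params.s is None else params.s
    sparse_active = s < math.sqrt(p) - 1e-12
    rng = np.random.default_rng(params.seed)

    n_init = 1 if init_centers is not None else params.n_init
    best: ClusteringResult | None = None
    for _ in range(n_init):
        w = np.full(p, 1.0 / math.sqrt(p))
        centers = (np.array(init_centers, dtype=float) if init_centers is not None
                   else _kmeanspp(X, k, w, rng, n_trim=n_trim))
        O_W: set[int] = set()
        O_E: set[int] = set()
        labels = np.zeros(n, dtype=int)
        objective_history: list[float] = []
        for _ in range(params.max_iter):
            labels, centers, O_W = _trimmed_kmeans(X, k, w, n_trim, rng, centers)
            # unweighted re-centering on cases outside O_W, then flag O_E
            keep_w = np.ones(n, dtype=bool)
            keep_w[list(O_W)] = False
            centers_u = np.vstack([
                X[keep_w & (labels == c)].mean(0) if (keep_w & (labels == c)).any()
                else centers[c] for c in range(k)])
            du = ((X - centers_u[labels]) ** 2).sum(1)
            if n_trim > 0:
                O_E = set(int(i) for i in np.argpartition(du, n - n_trim)[n - n_trim:])
            else:
                O_E = set()
            keep = np.ones(n, dtype=bool)
            keep[list(O_W | O_E)] = False
            b = _bcss_per_feature(X[keep], labels[keep])
            w_new = _soft_threshold_weights(b, s) if sparse_active else w
            objective_history.append(float(w_new @ b))
            if np.abs(w_new - w).max() < params.tol:
                w = w_new
                break
            w = w_new
        # final assignment of every case to the nearest weighted center
        D = _weighted_sq_dist(X, centers, w)
        labels = D.argmin(1)
        labels = _ensure_nonempty_labels(X, labels, k, centers)
        keep = np.ones(n, dtype=bool)
        keep[list(O_W | O_E)] = False
        b = _bcss_per_feature(X[keep], labels[keep]) if keep.any() else np.zeros(p)
        objective = float(w @ b)
        within = float(((X - centers[labels]) ** 2).sum())
        # restart selection uses the trimmed weighted within-cluster SS: the
        # robust criterion (a between-cluster criterion would reward restarts
        # whose centers capture gross outliers)
        dmin = _weighted_sq_dist(X, centers, w)[np.arange(n), labels]
        trim_wcss = float(dmin[keep].sum())
        result = ClusteringResult(
            labels=labels + 1, k=k, algorithm="rskc", weights=w,
            trimmed_weighted=frozenset(O_W), trimmed_unweighted=frozenset(O_E),
            objective=objective, wcss=within, seed=params.seed,
            extras={"objective_history": objective_history, "centers": centers,
                    "trimmed_wcss": trim_wcss},
        )
        if best is None or trim_wcss < best.extras["trimmed_wcss"]:
            best = result
    return best
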