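"""Adapters giving every clustering algorithm a uniform contract.

Each adapter returns a :class:`ClusteringResult` with exactly ``k``
non-empty clusters when feasible, 1-based labels, and is deterministic
given its seed.  K-means variants and the Gaussian mixture delegate to
scikit-learn; CLARA (PAM on random subsamples) and the self-organizing map
are implemented here; RSKC lives in :mod:`sepclust.cluster.rskc`.  Further
algorithms (e.g. a deep-clustering auto-encoder) can be plugged in through
:func:`register_algorithm`.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.mixture import GaussianMixture

from .base import ClusteringResult, _ensure_nonempty_labels


def _finalize(X, labels0, k, algorithm, seed, weights=None) -> ClusteringResult:
    labels0 = _ensure_nonempty_labels(X, labels0, k)
    p = X.shape[1]
    w = np.full(p, 1.0 / math.sqrt(p)) if weights is None else weights
    centers = np.vstack([X[labels0 == c].mean(0) for c in range(k)])
    within = float(((X - centers[labels0]) ** 2).sum())
    grand = X.mean(0)
    between = float(sum((labels0 == c).sum() * ((centers[c] - grand) ** 2 * w).sum()
                        for c in range(k)))
    return ClusteringResult(labels=labels0 + 1, k=k, algorithm=algorithm,
                            weights=w, objective=between, wcss=within, seed=seed)


def _kmeans(X, k, params, seed):
    n_init = params.get("n_init", 10)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return _finalize(X, km.labels_, k, "kmeans", seed)


def _minibatch_kmeans(X, k, params, seed):
    km = MiniBatchKMeans(n_clusters=k, n_init=params.get("n_init", 10),
                         batch_size=params.get("batch_size", 256),
                         random_state=seed).fit(X)
    return _finalize(X, km.labels_, k, "minibatch_kmeans", seed)


def _weighted_kmeans(X, k, params, seed):
    """K-means under fixed user-supplied feature weights.

    Weighted squared distance sum_j w_j (x_j - c_j)^2 equals the Euclidean
    distance after scaling features by sqrt(w_j), so delegate to K-means on
    the scaled matrix; centers/labels translate back unchanged.
    """
    p = X.shape[1]
    w = np.asarray(params.get("feature_weights", np.full(p, 1.0 / p)), dtype=float)
    if w.shape != (p,) or (w < 0).any():
        raise ValueError("feature_weights must be a nonnegative length-p vector")
    km = KMeans(n_clusters=k, n_init=params.get("n_init", 10),
                random_state=seed).fit(X * np.sqrt(w))
    return _finalize(X, km.labels_, k, "weighted_kmeans", seed, weights=w)


def _gmm(X, k, params, seed):
    gm = GaussianMixture(n_components=k,
                         covariance_type=params.get("covariance_type", "diag"),
                         reg_covar=params.get("reg_covar", 1e-4),
                         n_init=params.get("n_init", 2),
                         random_state=seed).fit(X)
    return _finalize(X, gm.predict(X), k, "gmm", seed)


def _rskc_adapter(X, k, params, seed):
    from .rskc import RskcParams, rskc
    rp = RskcParams(alpha=params.get("alpha", 0.1), s=params.get("s"),
                    n_init=params.get("n_init", 10),
                    max_iter=params.get("max_iter", 50),
                    tol=params.get("tol", 1e-4), seed=seed)
    return rskc(X, k, rp)


# ---------------------------------------------------------------------------
# CLARA: PAM applied to random subsamples, best medoid set kept
# ---------------------------------------------------------------------------

def _pam(X: np.ndarray, k: int, rng: np.random.Generator,
         max_swaps: int = 200) -> np.ndarray:
    """Partitioning Around Medoids (build + swap) on a small matrix.

    Returns the medoid row indices.  The build phase greedily picks medoids
    minimizing total dissimilarity; the swap phase applies first-improvement
    swaps until none improves.
    """
    n = X.shape[0]
    D = np.sqrt(np.maximum(
        (X ** 2).sum(1)[:, None] - 2 * X @ X.T + (X ** 2).sum(1)[None, :], 0.0))
    medoids = [int(D.sum(1).argmin())]
    while len(medoids) < k:
        dmin = D[:, medoids].min(1)
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids = np.array(medoids)

    def cost(meds):
        return D[:, meds].min(1).sum()

    current = cost(medoids)
    for _ in range(max_swaps):
        improved = False
        non_medoids = rng.permutation(np.setdiff1d(np.arange(n), medoids))
        for h in non_medoids:
            for i in range(k):
                trial = medoids.copy()
                trial[i] = h
                c = cost(trial)
                if c < current - 1e-12:
                    medoids, current, improved = trial, c, True
                    break
            if improved:
                break
        if not improved:
            break
    return medoids


def _clara(X, k, params, seed):
    """CLARA: PAM on up to 5 random subsamples of size 40 + 2k, keeping the
    medoid set with the lowest total dissimilarity on the full data."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    sample_size = min(n, params.get("sample_size", 40 + 2 * k))
    n_samples = params.get("n_samples", 5)
    best_meds, best_cost = None, np.inf
    for _ in range(n_samples):
        idx = rng.choice(n, size=sample_size, replace=False)
        meds_local = _pam(X[idx], k, rng)
        meds = idx[meds_local]
        d = np.sqrt(((X[:, None, :] - X[meds][None, :, :]) ** 2).sum(-1))
        c = d.min(1).sum()
        if c < best_cost:
            best_meds, best_cost = meds, c
    d = np.sqrt(((X[:, None, :] - X[best_meds][None, :, :]) ** 2).sum(-1))
    return _finalize(X, d.argmin(1), k, "clara", seed)


# ---------------------------------------------------------------------------
# SOM: online self-organizing map, units grouped into k clusters
# ---------------------------------------------------------------------------

def _som(X, k, params, seed):
    """Train a square SOM (smallest grid with >= 4k units), then group unit
    codebooks into k clusters by K-means; each case maps through its
    best-matching unit."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    g = math.ceil(math.sqrt(4 * k))
    units = g * g
    epochs = params.get("epochs", 10)
    coords = np.array([(i, j) for i in range(g) for j in range(g)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    codebook = X[rng.choice(n, size=units, replace=n < units)] + rng.normal(0, 0.01, (units, p))

    t_max = epochs * n
    t = 0
    sigma0, sigma_end = g / 2.0, 0.5
    lr0, lr_end = 0.5, 0.02
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = t / max(t_max - 1, 1)
            sigma = sigma0 * (sigma_end / sigma0) ** frac
            lr = lr0 * (lr_end / lr0) ** frac
            x = X[i]
            bmu = ((codebook - x) ** 2).sum(1).argmin()
            h = np.exp(-grid_d2[bmu] / (2 * sigma ** 2))
            codebook += lr * h[:, None] * (x - codebook)
            t += 1

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(codebook)
    bmus = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(-1).argmin(1)
    return _finalize(X, km.labels_[bmus], k, "som", seed)


ALGORITHMS: dict[str, Callable] = {
    "kmeans": _kmeans,
    "minibatch_kmeans": _minibatch_kmeans,
    "weighted_kmeans": _weighted_kmeans,
    "rskc": _rskc_adapter,
    "gmm": _gmm,
    "clara": _clara,
    "som": _som,
}


def register_algorithm(name: str, fn: Callable) -> None:
    """Plug in an external algorithm: fn(X, k, params, seed) -> ClusteringResult."""
    ALGORITHMS[name] = fn


def run_algorithm(name: str, X, k: int, params: dict | None = None,
                  seed: int = 0) -> ClusteringResult:
    """Run a registered algorithm under the uniform adapter contract."""
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; registered: {sorted(ALGORITHMS)}")
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of cases")
    return ALGORITHMS[name](X, k, params or {}, seed)
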