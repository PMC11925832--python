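"""Variable reduction: Kaiser-Meyer-Olkin filtering followed by PCA.

The KMO measure of sampling adequacy compares squared correlations to
squared partial correlations; variables whose per-variable MSA falls below a
floor (default 0.6) contribute little shared variance and are removed before
PCA.  PCA then retains the smallest number of components whose cumulative
explained-variance ratio reaches the target (default 95%).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReductionConfig:
    kmo_min: float = 0.6
    var_target: float = 0.95
    kmo_mode: str = "iterative"  # or "single_pass"

    def __post_init__(self) -> None:
        if not 0 <= self.kmo_min < 1:
            raise ValueError("kmo_min must lie in [0, 1)")
        if not 0 < self.var_target <= 1:
            raise ValueError("var_target must lie in (0, 1]")
        if self.kmo_mode not in ("iterative", "single_pass"):
            raise ValueError("kmo_mode must be 'iterative' or 'single_pass'")


@dataclass
class ComponentMatrix:
    scores: pd.DataFrame       # n x m principal-component scores
    loadings: pd.DataFrame     # p x m orthonormal directions
    explained_ratio: np.ndarray
    kept_features: list[str]

    def write(self, out_dir, msa: dict[str, float] | None = None,
              dropped: list[str] | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "components.csv")
        self.loadings.to_csv(out / "loadings.csv")
        report = {
            "explained_ratio": [float(r) for r in self.explained_ratio],
            "n_components": int(self.scores.shape[1]),
            "kept_features": self.kept_features,
            "per_variable_msa": msa or {},
            "dropped_by_kmo": dropped or [],
        }
        (out / "reduction_report.json").write_text(json.dumps(report, indent=2))


def _as_array(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, FeatureMatrix):
        return m.values.to_numpy(dtype=float), list(m.values.columns)
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), list(m.columns)
    arr = np.asarray(m, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def kmo(m) -> tuple[float, pd.Series]:
    """Overall KMO and per-variable MSA.

    With R the correlation matrix and P the partial-correlation matrix
    derived from the (pseudo-)inverse of R
    (p_ij = -r^ij / sqrt(r^ii r^jj)), the overall statistic is
    sum(R_ij^2) / (sum(R_ij^2) + sum(P_ij^2)) over off-diagonal pairs;
    MSA_j restricts both sums to row j.  An exactly diagonal R (all
    correlations zero) makes both sums vanish; 0 is returned with a warning.
    """
    X, names = _as_array(m)
    if X.shape[1] < 2:
        raise ValueError("kmo requires at least 2 columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; using pseudo-inverse")
        Rinv = np.linalg.pinv(R)
    diag = np.clip(np.diag(Rinv), 1e-12, None)  # guard near-singular R
    d = np.sqrt(np.outer(diag, diag))
    P = -Rinv / d
    off = ~np.eye(len(names), dtype=bool)
    r2 = np.where(off, R ** 2, 0.0)
    p2 = np.where(off, P ** 2, 0.0)
    denom_rows = r2.sum(axis=1) + p2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        msa = np.where(denom_rows > 0, r2.sum(axis=1) / denom_rows, 0.0)
    denom = r2.sum() + p2.sum()
    if denom == 0:
        warnings.warn("all correlations zero; KMO undefined, returning 0")
        overall = 0.0
    else:
        overall = float(r2.sum() / denom)
    return overall, pd.Series(msa, index=names)


def kmo_filter(m: FeatureMatrix, cfg: ReductionConfig = ReductionConfig()) -> FeatureMatrix:
    """Drop variables with MSA below the floor.

    ``single_pass`` removes all sub-floor variables at once; ``iterative``
    removes the single worst variable and recomputes until all pass (the
    standard MSA practice, since removing one variable changes the rest).
    """
    if cfg.kmo_min == 0:
        return m
    out = m.copy()
    if cfg.kmo_mode == "single_pass":
        _, msa = kmo(out)
        bad = list(msa.index[msa < cfg.kmo_min])
        if len(bad) == out.values.shape[1]:
            raise ValueError("KMO filter would drop every column")
        return out.drop(bad, "kmo")
    while True:
        _, msa = kmo(out)
        if (msa >= cfg.kmo_min).all():
            return out
        worst = msa.idxmin()
        if out.values.shape[1] <= 2:
            raise ValueError("KMO filter would drop every column")
        out = out.drop([worst], "kmo")


def pca_reduce(m, cfg: ReductionConfig = ReductionConfig()) -> ComponentMatrix:
    """PCA keeping the fewest components reaching the variance target.

    Operates on the covariance of the (already standardized) input, so this
    is correlation-scale PCA.  Eigenvector signs are fixed by forcing the
    largest-magnitude loading of each component positive, which makes the
    output reproducible across linear-algebra backends.
    """
    X, names = _as_array(m)
    n = X.shape[0]
    if n < 2:
        raise ValueError("pca_reduce requires n >= 2 rows")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    ratios = var / var.sum()
    cum = np.cumsum(ratios)
    n_keep = int(np.searchsorted(cum, cfg.var_target - 1e-12) + 1)
    n_keep = min(n_keep, len(ratios))
    V = Vt[:n_keep].T  # p x m
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(n_keep)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Xc @ V
    index = m.values.index if isinstance(m, FeatureMatrix) else (
        m.index if isinstance(m, pd.DataFrame) else pd.RangeIndex(n))
    pc_names = [f"PC{j+1}" for j in range(n_keep)]
    return ComponentMatrix(
        scores=pd.DataFrame(scores, index=index, columns=pc_names),
        loadings=pd.DataFrame(V, index=names, columns=pc_names),
        explained_ratio=ratios[:n_keep],
        kept_features=names,
    )


def reduce_pipeline(m: FeatureMatrix, cfg: ReductionConfig = ReductionConfig()
                    ) -> tuple[FeatureMatrix, ComponentMatrix]:
    """KMO filter then PCA; returns the post-KMO matrix and the components.

    The post-KMO matrix is what the downstream membership model trains on;
    the component scores are what clustering consumes.
    """
    kept = kmo_filter(m, cfg)
    comps = pca_reduce(kept, cfg)
    return kept, comps
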