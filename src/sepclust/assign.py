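"""External-cohort cluster assignment with a boosted-tree membership model.

A multi-class XGBoost model is trained on the development cohort's cluster
labels using the post-KMO variables (not the PCA scores), with
hyperparameters chosen by sequential model-based (Bayesian) optimization of
mean cross-validated accuracy — a Gaussian-process surrogate with expected
improvement; random search is available as a fallback.  Validation-cohort
patients are assigned to the cluster with the highest predicted
probability.  Feature attributions are exact tree-SHAP values (additive per
class: baseline + contributions = model margin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import norm, pearsonr
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold, cross_val_score

logger = logging.getLogger(__name__)

#: tuning space: name -> (low, high, is_log, is_int)
SEARCH_SPACE = {
    "learning_rate": (0.01, 0.3, True, False),
    "max_depth": (2, 8, False, True),
    "subsample": (0.5, 1.0, False, False),
    "n_estimators": (50, 300, False, True),
}


@dataclass
class MembershipModel:
    model: xgb.XGBClassifier
    feature_names: list[str]
    classes: np.ndarray  # original cluster ids, ascending
    tuned_params: dict
    cv_score: float
    seed: int


@dataclass
class AttributionMatrix:
    """Per (row, class, feature) additive attributions plus baselines."""

    values: np.ndarray       # (n, n_classes, n_features)
    baseline: np.ndarray     # (n, n_classes)
    feature_names: list[str]
    classes: np.ndarray

    def margins(self) -> np.ndarray:
        return self.baseline + self.values.sum(axis=2)

    def top_features(self, q: int = 10) -> pd.DataFrame:
        """Top-q features per class by mean |attribution|."""
        rows = []
        mean_abs = np.abs(self.values).mean(axis=0)  # (n_classes, n_features)
        for ci, cls in enumerate(self.classes):
            order = np.argsort(mean_abs[ci])[::-1][:q]
            for rank, j in enumerate(order, 1):
                rows.append({"cluster": cls, "rank": rank,
                             "feature": self.feature_names[j],
                             "mean_abs_attribution": float(mean_abs[ci, j])})
        return pd.DataFrame(rows)


def _decode(x: np.ndarray) -> dict:
    params = {}
    for val, (name, (lo, hi, is_log, is_int)) in zip(x, SEARCH_SPACE.items()):
        if is_log:
            v = float(np.exp(np.log(lo) + val * (np.log(hi) - np.log(lo))))
        else:
            v = float(lo + val * (hi - lo))
        params[name] = int(round(v)) if is_int else v
    return params


def _make_model(params: dict, n_classes: int, seed: int) -> xgb.XGBClassifier:
    # objective left implicit: softmax multi-class for >2 classes,
    # logistic for 2 (explicit multi:softprob breaks sklearn scoring at k=2)
    return xgb.XGBClassifier(tree_method="hist", n_jobs=1, random_state=seed,
                             verbosity=0, **params)


def bayes_optimize(objective, budget: int, seed: int, n_initial: int = 8,
                   method: str = "bayes") -> tuple[dict, float, list]:
    """Maximize ``objective(params)`` over SEARCH_SPACE within ``budget`` calls.

    Sequential model-based optimization: random exploration for the first
    points, then a Matern-kernel Gaussian process selects the candidate with
    the highest expected improvement among random proposals.
    ``method='random'`` disables the surrogate.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    dim = len(SEARCH_SPACE)
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []
    history = []
    n_initial = min(n_initial, budget)
    for t in range(budget):
        if t < n_initial or method == "random":
            x = rng.random(dim)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.full(dim, 0.3)),
                alpha=1e-4, normalize_y=True, random_state=seed)
            gp.fit(np.vstack(X_obs), np.asarray(y_obs))
            cand = rng.random((256, dim))
            mu, sd = gp.predict(cand, return_std=True)
            best_y = max(y_obs)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best_y) / sd
                ei = np.where(sd > 0, (mu - best_y) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
            x = cand[int(np.argmax(ei))]
        params = _decode(x)
        score = objective(params)
        X_obs.append(x)
        y_obs.append(score)
        history.append((params, score))
    best_i = int(np.argmax(y_obs))
    return history[best_i][0], float(y_obs[best_i]), history


def fit_membership_model(X_dev, labels, budget: int = 30, seed: int = 0,
                         n_folds: int = 5, method: str = "bayes",
                         scoring: str = "accuracy") -> MembershipModel:
    """Fit the cluster-membership model with tuned hyperparameters.

    ``X_dev`` is a DataFrame (or array) of the post-KMO variables; every
    class needs at least 2 rows.  ``budget`` counts hyperparameter
    evaluations; ``budget=1`` fits one randomly drawn configuration.
    """
    X = X_dev.to_numpy(dtype=float) if isinstance(X_dev, pd.DataFrame) else np.asarray(X_dev, dtype=float)
    names = (list(X_dev.columns) if isinstance(X_dev, pd.DataFrame)
             else [f"x{j}" for j in range(X.shape[1])])
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    counts = np.bincount(y)
    thin = classes[counts < 2]
    if len(thin):
        raise ValueError(f"classes with a single training row: {list(thin)}")
    folds = min(n_folds, int(counts.min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)

    def objective(params: dict) -> float:
        model = _make_model(params, len(classes), seed)
        return float(cross_val_score(model, X, y, cv=cv, scoring=scoring).mean())

    best_params, best_score, _ = bayes_optimize(objective, budget, seed, method=method)
    model = _make_model(best_params, len(classes), seed)
    model.fit(X, y)
    logger.info("membership model tuned: %s (cv %s=%.4f)", best_params, scoring, best_score)
    return MembershipModel(model=model, feature_names=names, classes=classes,
                           tuned_params=best_params, cv_score=best_score, seed=seed)


def predict_proba(mm: MembershipModel, X_new) -> np.ndarray:
    if isinstance(X_new, pd.DataFrame):
        missing = set(mm.feature_names) - set(X_new.columns)
        if missing:
            raise ValueError(f"missing feature columns: {sorted(missing)}")
        X_new = X_new[mm.feature_names]
    X = np.asarray(X_new, dtype=float)
    return mm.model.predict_proba(X)


def assign_clusters(mm: MembershipModel, X_new) -> np.ndarray:
    """Max-probability assignment; ties go to the smallest cluster id."""
    proba = predict_proba(mm, X_new)
    best = proba.max(axis=1, keepdims=True)
    ties = (np.isclose(proba, best).sum(axis=1) > 1).sum()
    if ties:
        logger.info("%d rows had tied maximum probabilities", int(ties))
    return mm.classes[proba.argmax(axis=1)]  # argmax -> first (smallest id)


def feature_attribution(mm: MembershipModel, X) -> AttributionMatrix:
    """Exact tree-SHAP attributions per class (additive to the margin)."""
    if isinstance(X, pd.DataFrame):
        X = X[mm.feature_names]
    X = np.asarray(X, dtype=float)
    booster = mm.model.get_booster()
    contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
    # multiclass shape: (n, n_classes, n_features + 1); last slot is the bias.
    # Binary models emit one margin (positive class); the class-0 margin of a
    # logistic model is its negation, so mirror with a sign flip.
    if contribs.ndim == 2:
        contribs = np.stack([-contribs, contribs], axis=1)
    return AttributionMatrix(values=contribs[:, :, :-1], baseline=contribs[:, :, -1],
                             feature_names=mm.feature_names, classes=mm.classes)


def compare_cohorts(dev_comp: pd.DataFrame, val_comp: pd.DataFrame,
                    ) -> tuple[float, float]:
    """Pearson correlation of per-cluster ASE(+) fractions across cohorts.

    Both inputs are cluster-composition frames (columns ``cluster`` and
    ``frac_ase_pos``); cluster id sets must match.  Returns (r, p_value).
    """
    dev = dev_comp.set_index("cluster")["frac_ase_pos"]
    val = val_comp.set_index("cluster")["frac_ase_pos"]
    if set(dev.index) != set(val.index):
        raise ValueError("cohorts must share the same cluster id set")
    val = val.reindex(dev.index)
    if dev.nunique() < 2 or val.nunique() < 2:
        raise ValueError("constant ASE-fraction vector; correlation undefined")
    r, p = pearsonr(dev.to_numpy(), val.to_numpy())
    return float(r), float(p)


def cohort_std_diffs(dev: pd.DataFrame, val: pd.DataFrame,
                     variables: dict[str, str]) -> pd.DataFrame:
    """Variable-wise standardized differences between two cohorts.

    ``variables`` maps column name -> 'continuous' | 'binary'.
    """
    from .ase import standardized_difference

    rows = []
    for var, kind in variables.items():
        if kind == "continuous":
            g1 = (dev[var].mean(), dev[var].std())
            g2 = (val[var].mean(), val[var].std())
        else:
            g1 = float(dev[var].mean())
            g2 = float(val[var].mean())
        d, cls = standardized_difference(g1, g2, kind)
        rows.append({"variable": var, "kind": kind, "d": d, "effect": cls})
    return pd.DataFrame(rows)
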