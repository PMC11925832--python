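"""Feature-matrix construction from encounter and event tables.

The pipeline mirrors standard EHR phenotyping practice: repeatedly measured
labs are summarized per patient by their minimum, maximum and standard
deviation over time (extremes and fluctuation of physiological state);
life-support and medication events become indicator/count features;
categoricals are fully dummy-encoded; then rare binary features (<1%
prevalence) and highly collinear columns are removed, missing values are
mean-imputed, and continuous columns are z-scored.  Outcome variables
(death, discharge day) and raw timing variables never enter the matrix;
derived lengths of stay are retained.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: encounter columns never admitted as features
OUTCOME_COLUMNS = ("died", "discharged_alive_day")
ID_COLUMNS = ("patient_id",)


@dataclass
class PreprocessConfig:
    prevalence_min: float = 0.01
    collinearity_r_max: float = 0.9
    sd_convention: float = 0.0  # SD assigned to single-observation series

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_min < 1:
            raise ValueError("prevalence_min must lie in (0, 1)")
        if not 0 < self.collinearity_r_max <= 1:
            raise ValueError("collinearity_r_max must lie in (0, 1]")


@dataclass
class FeatureMatrix:
    """n x p numeric matrix plus per-column metadata.

    ``values`` is indexed by patient id; ``meta`` is indexed by feature name
    with columns kind ('binary'|'continuous'), summary ('min'|'max'|'sd'|
    'static'), and missing_fraction.  ``dropped`` records features removed
    later in the pipeline and why.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    def binary_columns(self) -> list[str]:
        return list(self.meta.index[self.meta["kind"] == "binary"])

    def continuous_columns(self) -> list[str]:
        return list(self.meta.index[self.meta["kind"] == "continuous"])

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.meta.copy(), dict(self.dropped))

    def drop(self, names: list[str], reason: str) -> "FeatureMatrix":
        for n in names:
            self.dropped[n] = reason
            logger.info("dropped feature %s (%s)", n, reason)
        return FeatureMatrix(self.values.drop(columns=names),
                             self.meta.drop(index=names), self.dropped)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(out / "features.csv")
        meta = self.meta.reset_index().rename(columns={"index": "name"})
        payload = {"features": meta.to_dict("records"), "dropped": self.dropped}
        (out / "features_meta.json").write_text(json.dumps(payload, indent=2))


def summarize_timeseries(events: pd.DataFrame, encounters: pd.DataFrame,
                         cfg: PreprocessConfig = PreprocessConfig()) -> FeatureMatrix:
    """Per-patient lab summaries (min/max/sample SD) and event counts.

    Lab rows with non-finite values are rejected with a warning.  Patients
    with no observation of a lab receive missing markers for its three
    summary columns.  Ventilation and vasopressor events yield any/day-count
    features; antimicrobial days and blood-culture draws yield counts.
    """
    pids = pd.Index(encounters["patient_id"], name="patient_id")
    labs = events[events["event_type"] == "lab"].copy()
    bad = ~np.isfinite(labs["value"].to_numpy(dtype=float))
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} lab rows with non-finite values")
        labs = labs.loc[~bad]

    cols: dict[str, pd.Series] = {}
    meta_rows: list[dict] = []
    for name, grp in labs.groupby("name", sort=True):
        agg = grp.groupby("patient_id")["value"].agg(["min", "max", "std", "count"])
        sd = agg["std"].where(agg["count"] > 1, cfg.sd_convention)
        for summary, series in (("min", agg["min"]), ("max", agg["max"]), ("sd", sd)):
            col = f"{name}_{summary}"
            cols[col] = series.reindex(pids)
            meta_rows.append({"name": col, "kind": "continuous", "summary": summary})

    def _day_counts(etype: str) -> pd.Series:
        sel = events[events["event_type"] == etype]
        return sel.groupby("patient_id")["day"].nunique().reindex(pids).fillna(0)

    for etype, label in (("vent", "vent"), ("vasopressor", "vaso")):
        days = _day_counts(etype)
        cols[f"{label}_any"] = (days > 0).astype(int)
        meta_rows.append({"name": f"{label}_any", "kind": "binary", "summary": "static"})
        cols[f"{label}_days"] = days.astype(float)
        meta_rows.append({"name": f"{label}_days", "kind": "continuous", "summary": "static"})
    cols["abx_days"] = _day_counts("antimicrobial").astype(float)
    meta_rows.append({"name": "abx_days", "kind": "continuous", "summary": "static"})
    cols["culture_count"] = _day_counts("blood_culture").astype(float)
    meta_rows.append({"name": "culture_count", "kind": "continuous", "summary": "static"})

    values = pd.DataFrame(cols, index=pids)
    meta = pd.DataFrame(meta_rows).set_index("name")
    meta["missing_fraction"] = values.isna().mean()
    return FeatureMatrix(values, meta)


def encode_categoricals(encounters: pd.DataFrame) -> FeatureMatrix:
    """Static encounter features: dummies for categoricals, passthrough else.

    Every categorical level becomes one 0/1 indicator (full encoding; levels
    absent in the data simply yield no column and prevalence filtering
    handles near-empty ones).  Outcome and id columns are excluded; numeric
    columns pass through, 0/1 columns typed binary.
    """
    df = encounters.drop(columns=[c for c in (*ID_COLUMNS, *OUTCOME_COLUMNS)
                                  if c in encounters.columns])
    df = df.set_axis(pd.Index(encounters["patient_id"], name="patient_id"))
    cols: dict[str, pd.Series] = {}
    meta_rows: list[dict] = []
    for col in df.columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            for level in sorted(s.dropna().unique()):
                name = f"{col}_{level}"
                cols[name] = (s == level).astype(int)
                meta_rows.append({"name": name, "kind": "binary", "summary": "static"})
        else:
            vals = s.astype(float)
            is_binary = vals.dropna().isin([0.0, 1.0]).all()
            cols[col] = vals
            meta_rows.append({"name": col, "kind": "binary" if is_binary else "continuous",
                              "summary": "static"})
    values = pd.DataFrame(cols)
    meta = pd.DataFrame(meta_rows).set_index("name")
    meta["missing_fraction"] = values.isna().mean()
    return FeatureMatrix(values, meta)


def combine(*parts: FeatureMatrix) -> FeatureMatrix:
    values = pd.concat([p.values for p in parts], axis=1)
    if values.columns.duplicated().any():
        dupes = list(values.columns[values.columns.duplicated()])
        raise ValueError(f"duplicate feature names: {dupes}")
    meta = pd.concat([p.meta for p in parts], axis=0)
    dropped: dict[str, str] = {}
    for p in parts:
        dropped.update(p.dropped)
    return FeatureMatrix(values, meta, dropped)


def filter_prevalence(m: FeatureMatrix,
                      cfg: PreprocessConfig = PreprocessConfig()) -> FeatureMatrix:
    """Remove binary columns with prevalence strictly below the floor."""
    to_drop = [c for c in m.binary_columns()
               if m.values[c].mean() < cfg.prevalence_min]
    return m.copy().drop(to_drop, "prevalence")


def filter_collinear(m: FeatureMatrix,
                     cfg: PreprocessConfig = PreprocessConfig()) -> FeatureMatrix:
    """Greedy pairwise collinearity pruning in column order.

    For each pair (i, j), i < j, with |Pearson r| above the cap (computed on
    pairwise-complete rows), the later column j is dropped.  Constant
    columns have undefined r, treated as 0.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = m.values.corr(min_periods=2).fillna(0.0).to_numpy()
    names = list(m.values.columns)
    dropped: set[int] = set()
    for i in range(len(names)):
        if i in dropped:
            continue
        for j in range(i + 1, len(names)):
            if j in dropped:
                continue
            if abs(corr[i, j]) > cfg.collinearity_r_max:
                dropped.add(j)
    return m.copy().drop([names[j] for j in sorted(dropped)], "collinearity")


def impute_mean(m: FeatureMatrix) -> FeatureMatrix:
    """Replace missing markers with column means; metadata preserved."""
    fully_missing = [c for c in m.values.columns if m.values[c].isna().all()]
    if fully_missing:
        raise ValueError(f"fully-missing columns cannot be imputed: {fully_missing}")
    out = m.copy()
    out.values = out.values.fillna(out.values.mean())
    return out


def standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Z-score continuous columns (population SD); binaries untouched.

    Constant continuous columns become all-zero with a warning.
    """
    out = m.copy()
    for c in out.continuous_columns():
        v = out.values[c].to_numpy(dtype=float)
        sd = v.std()  # population (n) denominator
        if sd == 0:
            warnings.warn(f"constant continuous column {c!r} set to zeros")
            out.values[c] = 0.0
        else:
            out.values[c] = (v - v.mean()) / sd
    return out


def preprocess_pipeline(encounters: pd.DataFrame, events: pd.DataFrame,
                        cfg: PreprocessConfig = PreprocessConfig()) -> FeatureMatrix:
    """summarize -> encode -> prevalence -> collinearity -> impute -> standardize."""
    ts = summarize_timeseries(events, encounters, cfg)
    stat = encode_categoricals(encounters)
    m = combine(stat, ts)
    m = filter_prevalence(m, cfg)
    m = filter_collinear(m, cfg)
    m = impute_mean(m)
    return standardize(m)
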