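"""Synthetic ICU cohort generator with planted cluster structure.

Every downstream stage of the pipeline (preprocessing, reduction, clustering,
assignment, ASE analysis) is exercised on cohorts produced here, because the
source patient data cannot be shared.  The generator emits three long-format
tables:

* encounters — one row per hospitalization (demographics, lengths of stay,
  outcome, comorbidity flags, a diagnosis chapter, and the planted
  continuous cluster features),
* events — day-stamped labs, antimicrobial days, blood-culture draws, and
  ventilation/vasopressor days,
* truth — the latent cluster id, septic flag and outlier flag per patient.

The latent structure is a Gaussian mixture: cluster means are drawn
N(0, delta^2) per coordinate, patients N(mu_c, I), with an epsilon fraction
of outliers drawn from an inflated-variance component N(mu_c, 25 I).
Patients in the designated septic clusters receive a blood-culture day, an
antimicrobial run and organ-dysfunction lab excursions crossing the default
Adult Sepsis Event thresholds with probability ``p_sev``, or landing between
the liberalized and default thresholds ("near miss") with probability
``p_mild``.  Background event rates for the remaining patients are tuned to
the marginal utilization rates of a mixed ICU population (blood cultures
~37%, antimicrobials ~59%, mechanical ventilation ~39%, vasopressors ~19%,
in-hospital mortality ~11%) while never generating a default-ASE-positive
patient outside the severe septic group (background antimicrobial runs stay
below four days).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DX_CHAPTERS = ("circulatory", "respiratory", "infectious", "digestive", "injury_poisoning")

#: reference (healthy-ish) lab baselines: (low, high) uniform ranges
LAB_BASELINES = {
    "lactate": (0.6, 1.4),
    "creatinine": (55.0, 95.0),
    "egfr": (85.0, 115.0),
    "bilirubin": (5.0, 14.0),
    "platelets": (180.0, 320.0),
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 600
    k_true: int = 4
    mix: tuple[float, ...] | None = None  # default: uniform
    n_cont: int = 10
    n_bin: int = 6
    separation: float = 5.0  # cluster-mean spread, in SD units
    contamination: float = 0.02  # outlier fraction
    septic_clusters: tuple[int, ...] = (1,)
    p_sev: float = 0.9
    p_mild: float = 0.1
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    #: seed for the latent cluster structure (means, Bernoulli rates,
    #: diagnosis mixtures).  Defaults to ``seed``.  Two cohorts generated
    #: with the same structure_seed but different seeds are independent
    #: samples from the same population — the development/validation design.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mix is None:
            self.mix = tuple(1.0 / self.k_true for _ in range(self.k_true))
        if len(self.mix) != self.k_true:
            raise ValueError("mix length must equal k_true")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix must sum to 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_patients and self.n_patients < self.k_true:
            raise ValueError("n_patients must be >= k_true")
        for name in ("contamination", "p_sev", "p_mild"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_sev + self.p_mild > 1 + 1e-12:
            raise ValueError("p_sev + p_mild must not exceed 1")
        if not set(self.septic_clusters) <= set(range(1, self.k_true + 1)):
            raise ValueError("septic_clusters must be a subset of {1..k_true}")
        for name, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")


_ENC_COLUMNS = ["patient_id", "age", "sex", "admit_via_ed", "icu_los", "hosp_los",
                "died", "discharged_alive_day", "dx_chapter"]
_EVT_COLUMNS = ["patient_id", "day", "event_type", "name", "value"]
_TRUTH_COLUMNS = ["patient_id", "true_cluster", "true_septic", "is_outlier"]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (encounters, events, truth); deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    srng = np.random.default_rng(cfg.seed if cfg.structure_seed is None
                                 else cfg.structure_seed)
    n, k = cfg.n_patients, cfg.k_true

    enc_cols = (_ENC_COLUMNS
                + [f"comorb_{j+1:02d}" for j in range(cfg.n_bin)]
                + [f"feat_{j+1:02d}" for j in range(cfg.n_cont)])
    if n == 0:
        return (pd.DataFrame(columns=enc_cols), pd.DataFrame(columns=_EVT_COLUMNS),
                pd.DataFrame(columns=_TRUTH_COLUMNS))

    cluster = rng.choice(np.arange(1, k + 1), size=n, p=np.asarray(cfg.mix))
    is_outlier = rng.random(n) < cfg.contamination
    septic = np.isin(cluster, cfg.septic_clusters)

    # planted continuous block (population structure from srng)
    mu = srng.normal(0.0, cfg.separation, size=(k, cfg.n_cont))
    X = rng.normal(0.0, 1.0, size=(n, cfg.n_cont))
    X[is_outlier] *= 5.0  # inflated-variance component N(mu_c, 25 I)
    X += mu[cluster - 1]

    # planted binary block: per-cluster Bernoulli rates
    pbin = srng.uniform(0.1, 0.6, size=(k, cfg.n_bin))
    B = (rng.random((n, cfg.n_bin)) < pbin[cluster - 1]).astype(int)

    # severity tier within septic clusters
    u = rng.random(n)
    severe = septic & (u < cfg.p_sev)
    mild = septic & ~severe & (u < cfg.p_sev + cfg.p_mild)

    # encounter-level characteristics (background rates tuned to ICU marginals)
    age = np.clip(rng.normal(62, 15, n).round(), 18, 95).astype(int)
    sex = np.where(rng.random(n) < 0.36, "F", "M")
    admit_ed = (rng.random(n) < (0.66 + 0.13 * septic)).astype(int)
    icu_los = np.maximum(1, rng.lognormal(np.log(3), 0.6, n).round()).astype(int)
    icu_los = np.where(septic, np.maximum(icu_los, 3), icu_los)
    extra = np.maximum(0, rng.lognormal(np.log(5), 0.7, n).round()).astype(int)
    hosp_los = icu_los + extra
    # septic encounters must be long enough to host a culture + antimicrobial run
    hosp_los = np.where(septic, np.maximum(hosp_los, 10), hosp_los)
    died = rng.random(n) < np.where(septic, 0.30, 0.06)

    dx_probs = srng.dirichlet(np.full(len(DX_CHAPTERS), 1.5), size=k)
    septic_dx = srng.dirichlet([1.0, 2.0, 3.0, 1.0, 1.0], size=k)  # infection-leaning
    dx = np.empty(n, dtype=object)
    for i in range(n):
        p = septic_dx[cluster[i] - 1] if septic[i] else dx_probs[cluster[i] - 1]
        dx[i] = DX_CHAPTERS[rng.choice(len(DX_CHAPTERS), p=p)]

    pids = [f"P{i+1:06d}" for i in range(n)]
    enc = pd.DataFrame({
        "patient_id": pids, "age": age, "sex": sex, "admit_via_ed": admit_ed,
        "icu_los": icu_los, "hosp_los": hosp_los, "died": died.astype(int),
        "discharged_alive_day": np.where(died, np.nan, hosp_los.astype(float)),
        "dx_chapter": dx,
    })
    for j in range(cfg.n_bin):
        enc[f"comorb_{j+1:02d}"] = B[:, j]
    for j in range(cfg.n_cont):
        enc[f"feat_{j+1:02d}"] = X[:, j]

    events = _generate_events(rng, enc, septic, severe, mild)
    if cfg.missing_rates:
        events = inject_missingness(events, cfg.missing_rates,
                                    seed=int(rng.integers(2**31 - 1)))

    truth = pd.DataFrame({
        "patient_id": pids, "true_cluster": cluster,
        "true_septic": septic.astype(int), "is_outlier": is_outlier.astype(int),
    })
    return enc[enc_cols], events, truth


def _generate_events(rng, enc, septic, severe, mild) -> pd.DataFrame:
    rows: list[tuple] = []
    n = len(enc)
    hosp_los = enc["hosp_los"].to_numpy()
    dad = enc["discharged_alive_day"].to_numpy()

    for i in range(n):
        pid = enc["patient_id"].iat[i]
        los = int(hosp_los[i])
        lab_days = list(range(1, min(los, 8) + 1))
        baselines = {lab: rng.uniform(lo, hi) for lab, (lo, hi) in LAB_BASELINES.items()}
        # piecewise-constant baselines with small measurement noise
        series = {lab: {d: baselines[lab] * (1 + rng.normal(0, 0.03)) for d in lab_days}
                  for lab in LAB_BASELINES}

        culture_day = None
        abx_days: set[int] = set()
        vent_days: set[int] = set()
        vaso_days: set[int] = set()

        if septic[i]:
            culture_day = int(rng.integers(2, min(los - 5, 5) + 1))
            w0, w1 = culture_day - 1, culture_day + 1  # excursion window
            if severe[i]:
                run_len = int(rng.integers(4, 8))
                abx_days = set(range(culture_day, min(culture_day + run_len, los) + 1))
                # guaranteed dysfunction: lactate excursion past the default threshold
                for d in range(w0, w1 + 1):
                    if d in series["lactate"]:
                        series["lactate"][d] = rng.uniform(2.5, 8.0)
                if rng.random() < 0.6:  # renal: creatinine >= 2x baseline
                    for d in range(w0, w1 + 1):
                        if d in series["creatinine"]:
                            series["creatinine"][d] = baselines["creatinine"] * rng.uniform(2.2, 4.0)
                            series["egfr"][d] = baselines["egfr"] * rng.uniform(0.2, 0.45)
                if rng.random() < 0.3:  # liver
                    for d in range(w0, w1 + 1):
                        if d in series["bilirubin"]:
                            series["bilirubin"][d] = max(40.0, baselines["bilirubin"] * 3.0)
                if rng.random() < 0.4:  # hematologic
                    for d in range(w0, w1 + 1):
                        if d in series["platelets"]:
                            series["platelets"][d] = rng.uniform(30.0, 90.0)
                if rng.random() < 0.55:
                    vent_days = set(range(culture_day, min(culture_day + int(rng.integers(2, 6)), los) + 1))
                if rng.random() < 0.5:
                    vaso_days = set(range(culture_day, min(culture_day + int(rng.integers(1, 4)), los) + 1))
            elif mild[i]:
                # near-miss: QAD 3 and labs between liberalized and default thresholds
                abx_days = set(range(culture_day, culture_day + 3))
                for d in range(w0, w1 + 1):
                    if d in series["lactate"]:
                        series["lactate"][d] = rng.uniform(1.6, 1.95)
                    if d in series["creatinine"]:
                        series["creatinine"][d] = baselines["creatinine"] * rng.uniform(1.6, 1.9)
            else:
                abx_days = set(range(culture_day, culture_day + int(rng.integers(1, 4))))
        else:
            # sterile organ derangements at ICU background rates (AKI,
            # thrombocytopenia, hyperlactatemia occur without sepsis); these
            # patients never reach 4 antimicrobial days so they stay
            # ASE-negative under the default criteria
            ex0 = int(rng.integers(1, max(los - 2, 2)))
            ex_days = range(ex0, min(ex0 + 2, los) + 1)
            if rng.random() < 0.30:  # hyperlactatemia
                for d in ex_days:
                    if d in series["lactate"]:
                        series["lactate"][d] = rng.uniform(2.1, 6.0)
            if rng.random() < 0.30:  # acute kidney injury
                for d in ex_days:
                    if d in series["creatinine"]:
                        series["creatinine"][d] = baselines["creatinine"] * rng.uniform(2.0, 3.5)
                        series["egfr"][d] = baselines["egfr"] * rng.uniform(0.25, 0.5)
            if rng.random() < 0.10:  # cholestasis / liver dysfunction
                for d in ex_days:
                    if d in series["bilirubin"]:
                        series["bilirubin"][d] = max(36.0, baselines["bilirubin"] * 2.5)
            if rng.random() < 0.20:  # thrombocytopenia
                for d in ex_days:
                    if d in series["platelets"]:
                        series["platelets"][d] = rng.uniform(40.0, 95.0)
            if rng.random() < 0.20:
                culture_day = int(rng.integers(1, los + 1))
            if rng.random() < 0.48:
                start = int(rng.integers(1, los + 1))
                run_len = int(rng.integers(1, 4))  # background runs stay below 4 days
                abx_days = set(range(start, min(start + run_len - 1, los) + 1))
            if rng.random() < 0.33:
                start = int(rng.integers(1, los + 1))
                vent_days = set(range(start, min(start + int(rng.integers(1, 5)), los) + 1))
            if rng.random() < 0.11:
                start = int(rng.integers(1, los + 1))
                vaso_days = set(range(start, min(start + int(rng.integers(1, 3)), los) + 1))

        for lab, vals in series.items():
            for d, v in vals.items():
                rows.append((pid, d, "lab", lab, round(float(v), 3)))
        if culture_day is not None:
            rows.append((pid, culture_day, "blood_culture", "blood_culture", np.nan))
        for d in sorted(abx_days):
            if 1 <= d <= los:
                rows.append((pid, d, "antimicrobial", "antimicrobial", np.nan))
        for d in sorted(vent_days):
            rows.append((pid, d, "vent", "vent", np.nan))
        for d in sorted(vaso_days):
            rows.append((pid, d, "vasopressor", "vasopressor", np.nan))

    return pd.DataFrame(rows, columns=_EVT_COLUMNS)


def inject_missingness(events: pd.DataFrame, rates: dict[str, float],
                       seed: int = 0) -> pd.DataFrame:
    """Independently delete lab observations per name with the given rates.

    Deletion removes the event row (the observation was never recorded);
    unknown names raise a warning and are ignored.  Reproducible given seed.
    """
    for r in rates.values():
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    known = set(events.loc[events["event_type"] == "lab", "name"])
    unknown = set(rates) - known
    if unknown:
        warnings.warn(f"missingness rates for unknown lab names ignored: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    drop = np.zeros(len(events), dtype=bool)
    is_lab = (events["event_type"] == "lab").to_numpy()
    names = events["name"].to_numpy()
    u = rng.random(len(events))
    for name, rate in rates.items():
        if name in known:
            drop |= is_lab & (names == name) & (u < rate)
    return events.loc[~drop].reset_index(drop=True)


def write_cohort(out_dir, enc: pd.DataFrame, events: pd.DataFrame,
                 truth: pd.DataFrame) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enc.to_csv(out / "encounters.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    p = Path(in_dir)
    enc = pd.read_csv(p / "encounters.csv")
    events = pd.read_csv(p / "events.csv")
    truth = pd.read_csv(p / "truth.csv")
    return enc, events, truth
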