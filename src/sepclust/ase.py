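"""Adult Sepsis Event (ASE) criteria engine.

Implements the CDC-style surveillance definition of sepsis at hospital-day
granularity: presumed infection (a blood-culture draw accompanied by a run of
qualifying antimicrobial days, QAD) together with at least one acute organ
dysfunction inside a day window around the culture.  All thresholds are
parameterized so that liberalized variants (lower lab thresholds, wider
windows, shorter antimicrobial runs, a discharged-alive rule) can be expressed
as alternative :class:`AseCriteria` objects.

Also provides the cluster-composition analyses built on ASE status:
ASE-majority/minority subdivision at the 50% boundary, cohort-share
summaries, reclassification of ASE-negative patients under liberalized
variants, and standardized differences between groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lab names the organ-dysfunction rules understand.
KNOWN_LABS = ("lactate", "creatinine", "egfr", "bilirubin", "platelets")

FLAG_CATEGORIES = ("respiratory", "renal", "liver", "hematologic", "cardiac", "lactate")


@dataclass(frozen=True)
class AseCriteria:
    """Thresholds defining one ASE variant.

    Defaults are the standard (strict) surveillance criteria: organ
    dysfunction within +/-2 days of a blood culture, >=4 qualifying
    antimicrobial days, creatinine doubling or eGFR halving, bilirubin
    >=34.2 umol/L with doubling, lactate >2.0 mmol/L, platelets <100e9/L
    with >=50% decline from an adequate (>=100) baseline.
    """

    variant_id: str = "default"
    window_days: int = 2
    min_qad: int = 4
    creat_ratio_min: float = 2.0
    egfr_decline_min: float = 0.50
    bili_abs_min: float = 34.2
    bili_ratio_min: float = 2.0
    lactate_min: float = 2.0
    platelet_abs_max: float = 100.0
    platelet_decline_min: float = 0.50
    #: platelet baseline adequacy floor; fixed across variants so that
    #: liberalizing platelet_abs_max never tightens the rule
    platelet_baseline_min: float = 100.0
    discharge_alive_qad_rule: bool = False

    def __post_init__(self) -> None:
        if self.window_days < 0:
            raise ValueError("window_days must be >= 0")
        if self.min_qad < 1:
            raise ValueError("min_qad must be >= 1")
        for name in ("creat_ratio_min", "bili_abs_min", "bili_ratio_min",
                     "lactate_min", "platelet_abs_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("egfr_decline_min", "platelet_decline_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


DEFAULT_CRITERIA = AseCriteria()


def liberalized_variants() -> list[AseCriteria]:
    """The ten liberalized ASE variants, ids ``a``..``j``.

    a-d relax single organ-dysfunction thresholds, e combines a-d,
    f/g widen the culture window to 3/4 days, h lowers the antimicrobial
    minimum to 3 days, i adds the discharged-alive antimicrobial rule,
    and j combines a, b, c, d, f, h and i.
    """
    base = DEFAULT_CRITERIA
    a = replace(base, variant_id="a", creat_ratio_min=1.5, egfr_decline_min=0.25)
    b = replace(base, variant_id="b", bili_abs_min=25.7, bili_ratio_min=1.5)
    c = replace(base, variant_id="c", lactate_min=1.5)
    d = replace(base, variant_id="d", platelet_abs_max=150.0, platelet_decline_min=0.25)
    e = replace(a, variant_id="e", bili_abs_min=25.7, bili_ratio_min=1.5,
                lactate_min=1.5, platelet_abs_max=150.0, platelet_decline_min=0.25)
    f = replace(base, variant_id="f", window_days=3)
    g = replace(base, variant_id="g", window_days=4)
    h = replace(base, variant_id="h", min_qad=3)
    i = replace(base, variant_id="i", discharge_alive_qad_rule=True)
    j = replace(e, variant_id="j", window_days=3, min_qad=3,
                discharge_alive_qad_rule=True)
    return [a, b, c, d, e, f, g, h, i, j]


@dataclass
class AseAssessment:
    """Per-encounter ASE determination under one criteria variant."""

    patient_id: object
    variant_id: str
    ase_positive: bool
    culture_day: int | None
    qad: int
    flags: dict[str, dict]  # category -> {"flag": bool, "day": int|None, "value": float|None}

    @property
    def n_organ_dysfunctions(self) -> int:
        return sum(1 for f in self.flags.values() if f["flag"])


def _antimicrobial_days(events: pd.DataFrame) -> np.ndarray:
    days = events.loc[events["event_type"] == "antimicrobial", "day"]
    return np.unique(days.to_numpy(dtype=int))


def _consecutive_runs(days: np.ndarray) -> list[tuple[int, int]]:
    """Sorted unique days -> list of (start, end) inclusive runs."""
    if days.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(days) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, days.size - 1]
    return [(int(days[s]), int(days[e])) for s, e in zip(starts, ends)]


def qualifying_antimicrobial_days(
    events: pd.DataFrame,
    culture_day: int,
    criteria: AseCriteria = DEFAULT_CRITERIA,
    discharged_alive_day: int | None = None,
) -> tuple[int, bool]:
    """Length of the longest qualifying antimicrobial run for one culture.

    A run qualifies for consideration when it is a maximal block of
    consecutive calendar days with at least one antimicrobial event and its
    first day lies within ``+/-window_days`` of ``culture_day``.  Returns
    ``(qad, qualifies)`` where ``qad`` is the longest such run length and
    ``qualifies`` additionally applies the discharged-alive rule: when
    enabled, a run that extends to ``discharged_alive_day`` qualifies
    regardless of ``min_qad``.
    """
    runs = _consecutive_runs(_antimicrobial_days(events))
    best = 0
    qualifies = False
    for start, end in runs:
        if abs(start - culture_day) > criteria.window_days:
            continue
        length = end - start + 1
        best = max(best, length)
        if length >= criteria.min_qad:
            qualifies = True
        elif (criteria.discharge_alive_qad_rule
              and discharged_alive_day is not None
              and end >= discharged_alive_day):
            qualifies = True
    return best, qualifies


def _lab_series(events: pd.DataFrame, name: str) -> pd.DataFrame:
    sel = events[(events["event_type"] == "lab") & (events["name"] == name)]
    return sel[["day", "value"]]


def _window(df: pd.DataFrame, culture_day: int, window: int) -> pd.DataFrame:
    return df[(df["day"] >= culture_day - window) & (df["day"] <= culture_day + window)]


def _first_day_where(df: pd.DataFrame, mask: pd.Series) -> int | None:
    hit = df.loc[mask, "day"]
    return int(hit.min()) if len(hit) else None


def organ_dysfunction_flags(
    events: pd.DataFrame,
    culture_day: int,
    criteria: AseCriteria = DEFAULT_CRITERIA,
) -> dict[str, dict]:
    """Evaluate the six ASE organ-dysfunction categories for one culture day.

    Lab baselines use the encounter extremum convention: minimum creatinine
    and bilirubin, maximum eGFR and platelets over the whole encounter; the
    dysfunction itself must occur inside the culture window.
    """
    unknown = set(events.loc[events["event_type"] == "lab", "name"]) - set(KNOWN_LABS)
    if unknown:
        warnings.warn(f"ignoring labs with unknown names: {sorted(unknown)}")

    w = criteria.window_days
    flags: dict[str, dict] = {}

    def _set(cat: str, flag: bool, day=None, value=None) -> None:
        flags[cat] = {"flag": bool(flag), "day": day, "value": value}

    for cat, etype in (("respiratory", "vent"), ("cardiac", "vasopressor")):
        days = events.loc[events["event_type"] == etype, "day"]
        days = days[(days >= culture_day - w) & (days <= culture_day + w)]
        _set(cat, len(days) > 0, int(days.min()) if len(days) else None)

    lact = _lab_series(events, "lactate")
    lw = _window(lact, culture_day, w)
    mask = lw["value"] > criteria.lactate_min  # strict > per the liberalized-threshold phrasing
    _set("lactate", mask.any(), _first_day_where(lw, mask),
         float(lw.loc[mask, "value"].max()) if mask.any() else None)

    creat = _lab_series(events, "creatinine")
    egfr = _lab_series(events, "egfr")
    renal = False
    renal_day = None
    renal_value = None
    if len(creat):
        baseline = float(creat["value"].min())
        cw = _window(creat, culture_day, w)
        if len(cw) and baseline > 0:
            ratio = cw["value"] / baseline
            mask = ratio >= criteria.creat_ratio_min
            if mask.any():
                renal = True
                renal_day = _first_day_where(cw, mask)
                renal_value = float(ratio.max())
    if not renal and len(egfr):
        baseline = float(egfr["value"].max())
        ew = _window(egfr, culture_day, w)
        if len(ew) and baseline > 0:
            decline = 1.0 - ew["value"] / baseline
            mask = decline >= criteria.egfr_decline_min
            if mask.any():
                renal = True
                renal_day = _first_day_where(ew, mask)
                renal_value = float(decline.max())
    _set("renal", renal, renal_day, renal_value)

    bili = _lab_series(events, "bilirubin")
    liver = False
    liver_day = None
    liver_value = None
    if len(bili):
        baseline = float(bili["value"].min())
        bw = _window(bili, culture_day, w)
        if len(bw) and baseline > 0:
            mask = (bw["value"] >= criteria.bili_abs_min) & (
                bw["value"] / baseline >= criteria.bili_ratio_min)
            if mask.any():
                liver = True
                liver_day = _first_day_where(bw, mask)
                liver_value = float(bw.loc[mask, "value"].max())
    _set("liver", liver, liver_day, liver_value)

    plate = _lab_series(events, "platelets")
    hema = False
    hema_day = None
    hema_value = None
    if len(plate):
        baseline = float(plate["value"].max())
        pw = _window(plate, culture_day, w)
        if len(pw) and baseline >= criteria.platelet_baseline_min:
            decline = 1.0 - pw["value"] / baseline
            mask = (pw["value"] < criteria.platelet_abs_max) & (
                decline >= criteria.platelet_decline_min)
            if mask.any():
                hema = True
                hema_day = _first_day_where(pw, mask)
                hema_value = float(pw.loc[mask, "value"].min())
    _set("hematologic", hema, hema_day, hema_value)

    return flags


def ase_status(
    encounter: Mapping,
    events: pd.DataFrame,
    criteria: AseCriteria = DEFAULT_CRITERIA,
) -> AseAssessment:
    """Assess one encounter against one ASE criteria variant.

    Positive iff some blood-culture day has a qualifying antimicrobial run
    and at least one organ-dysfunction flag inside the window; the first
    qualifying culture day is recorded.  ``encounter`` must expose
    ``patient_id`` and, for the discharged-alive rule, may expose
    ``discharged_alive_day``.
    """
    pid = encounter["patient_id"]
    dad = encounter.get("discharged_alive_day") if hasattr(encounter, "get") else (
        encounter["discharged_alive_day"] if "discharged_alive_day" in encounter else None)
    if dad is not None and not (isinstance(dad, (int, np.integer)) and not isinstance(dad, bool)):
        dad = int(dad) if np.isfinite(dad) else None

    culture_days = np.unique(
        events.loc[events["event_type"] == "blood_culture", "day"].to_numpy(dtype=int))
    empty_flags = {c: {"flag": False, "day": None, "value": None} for c in FLAG_CATEGORIES}
    if culture_days.size == 0:
        return AseAssessment(pid, criteria.variant_id, False, None, 0, empty_flags)

    best: tuple[int, int, dict] | None = None  # (culture_day, qad, flags) fallback record
    for cday in culture_days:
        qad, qualifies = qualifying_antimicrobial_days(
            events, int(cday), criteria, discharged_alive_day=dad)
        flags = organ_dysfunction_flags(events, int(cday), criteria)
        if best is None or qad > best[1]:
            best = (int(cday), qad, flags)
        if qualifies and any(f["flag"] for f in flags.values()):
            return AseAssessment(pid, criteria.variant_id, True, int(cday), qad, flags)
    cday, qad, flags = best
    return AseAssessment(pid, criteria.variant_id, False, cday, qad, flags)


def assess_cohort(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    criteria: AseCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """ASE status for every encounter; one row per patient.

    Returns a frame with patient_id, variant_id, ase_positive, culture_day,
    qad and one boolean column per organ-dysfunction category.
    """
    by_pid = dict(tuple(events.groupby("patient_id", sort=False)))
    empty = events.iloc[0:0]
    rows = []
    for enc in encounters.to_dict("records"):
        ev = by_pid.get(enc["patient_id"], empty)
        a = ase_status(enc, ev, criteria)
        row = {
            "patient_id": a.patient_id,
            "variant_id": a.variant_id,
            "ase_positive": a.ase_positive,
            "culture_day": a.culture_day,
            "qad": a.qad,
        }
        for cat in FLAG_CATEGORIES:
            row[f"flag_{cat}"] = a.flags[cat]["flag"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cluster composition against ASE status
# ---------------------------------------------------------------------------

def subdivide_clusters(labels: Sequence, ase_flags: Sequence[bool]) -> pd.DataFrame:
    """Per-cluster size, ASE(+) count/fraction and the >=50% majority flag."""
    labels = np.asarray(labels)
    flags = np.asarray(ase_flags, dtype=bool)
    if labels.shape[0] != flags.shape[0]:
        raise ValueError("labels and ase_flags must align")
    out = []
    for cid in np.unique(labels):
        sel = labels == cid
        size = int(sel.sum())
        if size == 0:
            raise ValueError(f"empty cluster id {cid}")
        npos = int(flags[sel].sum())
        frac = npos / size
        out.append({"cluster": cid, "size": size, "n_ase_pos": npos,
                    "frac_ase_pos": frac, "majority": frac >= 0.5})
    return pd.DataFrame(out)


def composition_summary(comp: pd.DataFrame, total_ase_pos: int) -> pd.DataFrame:
    """Majority/minority block shares, rounded to one decimal of a percent.

    For each block: number of clusters, patients, ASE(+) count, share of the
    cohort, within-block ASE(+) percentage, and share of all ASE(+) patients.
    """
    n_total = int(comp["size"].sum())
    maj_pos = int(comp.loc[comp["majority"], "n_ase_pos"].sum())
    if total_ase_pos < maj_pos:
        raise ValueError("total_ase_pos below majority-block ASE(+) count")
    if total_ase_pos == 0:
        warnings.warn("total_ase_pos is 0; ASE shares reported as 0")
    rows = []
    for block, sel in (("majority", comp["majority"]), ("minority", ~comp["majority"])):
        size = int(comp.loc[sel, "size"].sum())
        npos = int(comp.loc[sel, "n_ase_pos"].sum())
        rows.append({
            "block": block,
            "n_clusters": int(sel.sum()),
            "n_patients": size,
            "n_ase_pos": npos,
            "cohort_share_pct": round(100.0 * size / n_total, 1) if n_total else 0.0,
            "within_block_ase_pct": round(100.0 * npos / size, 1) if size else 0.0,
            "ase_share_pct": round(100.0 * npos / total_ase_pos, 1) if total_ase_pos else 0.0,
        })
    return pd.DataFrame(rows)


def reclassify_liberalized(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    variants: Iterable[AseCriteria] | None = None,
) -> pd.DataFrame:
    """Fraction of default-ASE-negative patients positive under each variant.

    ``encounters`` should already be restricted to the ASE(-) members of the
    ASE-majority clusters (the denominator).  Percentages use one decimal.
    """
    if variants is None:
        variants = liberalized_variants()
    variants = list(variants)
    denom = len(encounters)
    rows = []
    for crit in variants:
        flags = assess_cohort(encounters, events, crit)["ase_positive"] if denom else pd.Series([], dtype=bool)
        n = int(flags.sum())
        rows.append({"variant_id": crit.variant_id, "n_reclassified": n,
                     "pct": round(100.0 * n / denom, 1) if denom else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardized differences
# ---------------------------------------------------------------------------

_EFFECT_BOUNDS = ((0.2, "negligible"), (0.4, "small"), (0.8, "medium"))


def _effect_class(d: float) -> str:
    for bound, name in _EFFECT_BOUNDS:
        if abs(d) <= bound:
            return name
    return "large"


def standardized_difference(group1, group2, kind: str) -> tuple[float, str]:
    """Cohen's-d-style standardized difference between two groups.

    ``kind='continuous'``: groups are ``(mean, sd)`` pairs, d = (m2-m1) over
    the pooled SD sqrt((s1^2+s2^2)/2).  ``kind='binary'``: groups are
    proportions (or ``(count, n)`` pairs), d = (p2-p1) over
    sqrt((p1(1-p1)+p2(1-p2))/2).  Effect classed at |d| = 0.2 / 0.4 / 0.8.
    """
    if kind == "continuous":
        m1, s1 = group1
        m2, s2 = group2
        pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
        if pooled == 0:
            raise ZeroDivisionError("zero pooled SD")
        d = (m2 - m1) / pooled
    elif kind == "binary":
        p1 = group1[0] / group1[1] if isinstance(group1, (tuple, list)) and len(group1) == 2 else float(group1)
        p2 = group2[0] / group2[1] if isinstance(group2, (tuple, list)) and len(group2) == 2 else float(group2)
        pooled = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
        if pooled == 0:
            raise ZeroDivisionError("zero pooled SD")
        d = (p2 - p1) / pooled
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(d), _effect_class(d)
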