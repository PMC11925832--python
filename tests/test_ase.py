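"""Adult Sepsis Event engine: rules, variants, composition, std differences."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sepclust.ase import (DEFAULT_CRITERIA, AseCriteria, ase_status,
                          composition_summary, liberalized_variants,
                          organ_dysfunction_flags,
                          qualifying_antimicrobial_days,
                          reclassify_liberalized, standardized_difference,
                          subdivide_clusters)
from conftest import toy_encounter, toy_events


def _variant(vid):
    return next(v for v in liberalized_variants() if v.variant_id == vid)


def _abx(days):
    return [(d, "antimicrobial", "antimicrobial", np.nan) for d in days]


class TestQad:
    def test_run_length_counted(self):
        ev = toy_events(_abx(range(3, 8)))
        qad, ok = qualifying_antimicrobial_days(ev, 3, DEFAULT_CRITERIA)
        assert qad == 5 and ok

    def test_three_day_run_fails_default_passes_liberal(self):
        ev = toy_events(_abx(range(3, 6)))
        qad, ok = qualifying_antimicrobial_days(ev, 3, DEFAULT_CRITERIA)
        assert qad == 3 and not ok
        qad, ok = qualifying_antimicrobial_days(ev, 3, _variant("h"))
        assert qad == 3 and ok

    def test_discharge_alive_rule(self):
        """A short run ending on the discharged-alive day qualifies when the
        rule is on, regardless of the minimum-day threshold."""
        ev = toy_events(_abx([3, 4]))
        _, ok = qualifying_antimicrobial_days(ev, 3, DEFAULT_CRITERIA,
                                              discharged_alive_day=4)
        assert not ok
        _, ok = qualifying_antimicrobial_days(ev, 3, _variant("i"),
                                              discharged_alive_day=4)
        assert ok

    def test_gap_breaks_run(self):
        ev = toy_events(_abx([3, 4, 6, 7, 8, 9]))  # day 5 missing
        qad, ok = qualifying_antimicrobial_days(ev, 3, DEFAULT_CRITERIA)
        # run starting day 6 is outside +/-2 of culture day 3; run 3-4 counts
        assert qad == 2 and not ok

    def test_no_antimicrobials_zero(self):
        ev = toy_events([(1, "lab", "lactate", 1.0)])
        assert qualifying_antimicrobial_days(ev, 3, DEFAULT_CRITERIA) == (0, False)

    def test_run_start_outside_window_ignored(self):
        ev = toy_events(_abx(range(6, 12)))
        qad, ok = qualifying_antimicrobial_days(ev, 3, DEFAULT_CRITERIA)
        assert qad == 0 and not ok
        # window 3 admits a run starting on day 6
        qad, ok = qualifying_antimicrobial_days(ev, 3, _variant("f"))
        assert qad == 6 and ok


class TestOrganFlags:
    def test_creatinine_ratio_boundary(self):
        """Baseline 70 -> peak 126 is a 1.8-fold rise: below the default
        2.0-fold floor, above the liberalized 1.5-fold."""
        ev = toy_events([(1, "lab", "creatinine", 70.0),
                         (4, "lab", "creatinine", 126.0)])
        assert not organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)["renal"]["flag"]
        assert organ_dysfunction_flags(ev, 3, _variant("a"))["renal"]["flag"]

    def test_bilirubin_absolute_and_ratio(self):
        """Peak 30 with a 3x rise fails the default 34.2 absolute floor but
        passes the liberalized 25.7 floor."""
        ev = toy_events([(1, "lab", "bilirubin", 10.0),
                         (3, "lab", "bilirubin", 30.0)])
        assert not organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)["liver"]["flag"]
        assert organ_dysfunction_flags(ev, 3, _variant("b"))["liver"]["flag"]

    def test_lactate_threshold_strict(self):
        ev = toy_events([(4, "lab", "lactate", 1.8)])
        assert not organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)["lactate"]["flag"]
        assert organ_dysfunction_flags(ev, 3, _variant("c"))["lactate"]["flag"]
        # exactly at the threshold: strict > means no flag
        ev2 = toy_events([(4, "lab", "lactate", 2.0)])
        assert not organ_dysfunction_flags(ev2, 3, DEFAULT_CRITERIA)["lactate"]["flag"]

    def test_platelet_rule_with_baseline_floor(self):
        ev = toy_events([(1, "lab", "platelets", 220.0),
                         (4, "lab", "platelets", 80.0)])
        flags = organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)
        assert flags["hematologic"]["flag"]  # 80 < 100 and 64% decline
        # inadequate baseline (90 < 100): decline not interpretable
        ev2 = toy_events([(1, "lab", "platelets", 90.0),
                          (4, "lab", "platelets", 40.0)])
        assert not organ_dysfunction_flags(ev2, 3, DEFAULT_CRITERIA)["hematologic"]["flag"]

    def test_vent_and_vasopressor_in_window(self):
        ev = toy_events([(4, "vent", "vent", np.nan),
                         (9, "vasopressor", "vasopressor", np.nan)])
        flags = organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)
        assert flags["respiratory"]["flag"]
        assert not flags["cardiac"]["flag"]  # day 9 outside +/-2 of day 3

    def test_egfr_decline_route(self):
        ev = toy_events([(1, "lab", "egfr", 100.0), (3, "lab", "egfr", 45.0)])
        assert organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)["renal"]["flag"]

    def test_unknown_lab_warns(self):
        ev = toy_events([(3, "lab", "troponin", 5.0)])
        with pytest.warns(UserWarning, match="unknown"):
            organ_dysfunction_flags(ev, 3, DEFAULT_CRITERIA)


class TestAseStatus:
    def test_hand_traced_positive(self):
        """Culture day 3, antimicrobials 3-7, lactate 3.5 on day 4:
        positive with the lactate flag and QAD 5."""
        ev = toy_events([(3, "blood_culture", "blood_culture", np.nan),
                         *_abx(range(3, 8)),
                         (1, "lab", "lactate", 1.0),
                         (4, "lab", "lactate", 3.5)])
        a = ase_status(toy_encounter(), ev, DEFAULT_CRITERIA)
        assert a.ase_positive and a.qad == 5 and a.culture_day == 3
        assert a.flags["lactate"]["flag"]
        assert a.n_organ_dysfunctions == 1

    def test_no_culture_negative(self):
        ev = toy_events([*_abx(range(1, 9)), (2, "lab", "lactate", 9.0)])
        a = ase_status(toy_encounter(), ev, DEFAULT_CRITERIA)
        assert not a.ase_positive and a.culture_day is None
        assert not any(f["flag"] for f in a.flags.values())

    def test_window_boundary_day_plus_three(self):
        """Dysfunction on culture day + 3: negative at window 2, positive at
        window 3."""
        ev = toy_events([(3, "blood_culture", "blood_culture", np.nan),
                         *_abx(range(3, 8)),
                         (6, "lab", "lactate", 4.0)])
        assert not ase_status(toy_encounter(), ev, DEFAULT_CRITERIA).ase_positive
        assert ase_status(toy_encounter(), ev, _variant("f")).ase_positive

    def test_multiple_cultures_first_qualifying_day(self):
        ev = toy_events([(2, "blood_culture", "blood_culture", np.nan),
                         (6, "blood_culture", "blood_culture", np.nan),
                         *_abx(range(6, 11)),
                         (7, "lab", "lactate", 5.0)])
        a = ase_status(toy_encounter(), ev, DEFAULT_CRITERIA)
        assert a.ase_positive and a.culture_day == 6


class TestVariants:
    def test_ten_distinct_variants(self):
        vs = liberalized_variants()
        assert [v.variant_id for v in vs] == list("abcdefghij")
        assert DEFAULT_CRITERIA.variant_id not in {v.variant_id for v in vs}

    def test_combined_variant_covers_single_relaxation(self):
        """A patient positive only under the lactate relaxation (c) is also
        positive under the combined variant (j)."""
        ev = toy_events([(3, "blood_culture", "blood_culture", np.nan),
                         *_abx(range(3, 8)),
                         (4, "lab", "lactate", 1.8)])
        enc = toy_encounter()
        assert not ase_status(enc, ev, DEFAULT_CRITERIA).ase_positive
        assert ase_status(enc, ev, _variant("c")).ase_positive
        assert ase_status(enc, ev, _variant("j")).ase_positive

    def test_window_nesting_f_implies_g(self):
        ev = toy_events([(3, "blood_culture", "blood_culture", np.nan),
                         *_abx(range(3, 8)),
                         (6, "lab", "lactate", 4.0)])
        enc = toy_encounter()
        assert ase_status(enc, ev, _variant("f")).ase_positive
        assert ase_status(enc, ev, _variant("g")).ase_positive


def _random_toy_patient(rng):
    """Random small event history exercising every rule branch."""
    rows = []
    los = int(rng.integers(6, 15))
    if rng.random() < 0.8:
        rows.append((int(rng.integers(1, 6)), "blood_culture", "blood_culture", np.nan))
    if rng.random() < 0.9:
        start = int(rng.integers(1, 6))
        rows += _abx(range(start, start + int(rng.integers(1, 7))))
    for lab, lo, hi in (("lactate", 0.5, 4.0), ("creatinine", 50, 400),
                        ("egfr", 10, 120), ("bilirubin", 4, 80),
                        ("platelets", 20, 350)):
        for _ in range(int(rng.integers(0, 4))):
            rows.append((int(rng.integers(1, los + 1)), "lab", lab,
                         float(rng.uniform(lo, hi))))
    for etype in ("vent", "vasopressor"):
        if rng.random() < 0.3:
            rows.append((int(rng.integers(1, los + 1)), etype, etype, np.nan))
    enc = toy_encounter(discharged_alive_day=los if rng.random() < 0.7 else None)
    return enc, toy_events(rows)


#: fields relaxed toward positivity, with a strictly-more-liberal value map
_RELAXATIONS = {
    "window_days": lambda v: v + 1,
    "min_qad": lambda v: max(1, v - 1),
    "creat_ratio_min": lambda v: v * 0.75,
    "egfr_decline_min": lambda v: v * 0.5,
    "bili_abs_min": lambda v: v * 0.75,
    "bili_ratio_min": lambda v: v * 0.75,
    "lactate_min": lambda v: v * 0.75,
    "platelet_abs_max": lambda v: v * 1.5,
    "platelet_decline_min": lambda v: v * 0.5,
    "discharge_alive_qad_rule": lambda v: True,
}


class TestMonotonicityProperties:
    def test_single_threshold_relaxation_never_flips_positive(self):
        """Relaxing any one criterion keeps every positive patient positive
        (1,000 random toy patients x 10 thresholds)."""
        rng = np.random.default_rng(0)
        patients = [_random_toy_patient(rng) for _ in range(100)]
        for fieldname, relax in _RELAXATIONS.items():
            crit = dataclasses.replace(
                DEFAULT_CRITERIA, variant_id=f"relaxed_{fieldname}",
                **{fieldname: relax(getattr(DEFAULT_CRITERIA, fieldname))})
            for enc, ev in patients:
                if ase_status(enc, ev, DEFAULT_CRITERIA).ase_positive:
                    assert ase_status(enc, ev, crit).ase_positive, fieldname

    def test_variant_nesting_default_subset_of_each_subset_of_j(self):
        """positives(default) <= positives(a..i) and each <= positives(j)
        for the variants j actually combines (a-d, f, h, i)."""
        rng = np.random.default_rng(1)
        patients = [_random_toy_patient(rng) for _ in range(150)]
        vj = _variant("j")
        for enc, ev in patients:
            base = ase_status(enc, ev, DEFAULT_CRITERIA).ase_positive
            j_pos = ase_status(enc, ev, vj).ase_positive
            for v in liberalized_variants():
                v_pos = ase_status(enc, ev, v).ase_positive
                if base:
                    assert v_pos, v.variant_id
                if v_pos and v.variant_id in "abcdfhi":
                    assert j_pos, v.variant_id


class TestComposition:
    def test_majority_boundary_at_half(self):
        comp = subdivide_clusters([1, 1, 1, 1], [True, True, False, False])
        assert comp.loc[0, "frac_ase_pos"] == 0.5
        assert bool(comp.loc[0, "majority"])

    def test_all_negative_no_majority(self):
        comp = subdivide_clusters([1, 1, 2, 2], [False] * 4)
        assert not comp["majority"].any()

    def test_printed_development_counts_reproduce_percentages(self):
        """11 majority clusters (821 patients, 612 ASE+) and 37 minority
        clusters (2839 patients, 175 ASE+) give 74.5%/6.2% within-block and
        77.8%/22.2% shares of the 787 cohort ASE(+) patients."""
        comp = pd.DataFrame({
            "cluster": range(48),
            "size": [821 // 11 + (1 if i < 821 % 11 else 0) for i in range(11)]
                    + [2839 // 37 + (1 if i < 2839 % 37 else 0) for i in range(37)],
            "n_ase_pos": [612 // 11 + (1 if i < 612 % 11 else 0) for i in range(11)]
                         + [175 // 37 + (1 if i < 175 % 37 else 0) for i in range(37)],
        })
        comp["frac_ase_pos"] = comp["n_ase_pos"] / comp["size"]
        comp["majority"] = [True] * 11 + [False] * 37
        summary = composition_summary(comp, total_ase_pos=787).set_index("block")
        assert summary.loc["majority", "within_block_ase_pct"] == 74.5
        assert summary.loc["majority", "ase_share_pct"] == 77.8
        assert summary.loc["minority", "within_block_ase_pct"] == 6.2
        assert summary.loc["minority", "ase_share_pct"] == 22.2
        # conservation of counts
        assert summary["n_patients"].sum() == 3660
        assert summary["n_ase_pos"].sum() == 787

    def test_zero_total_warns(self):
        comp = subdivide_clusters([1, 1], [False, False])
        with pytest.warns(UserWarning):
            s = composition_summary(comp, 0)
        assert (s["ase_share_pct"] == 0).all()

    def test_reclassification_percentage_convention(self):
        """12 of 209 -> 5.7% at one decimal, matching the variant-a row."""
        assert round(100 * 12 / 209, 1) == 5.7
        enc = pd.DataFrame({"patient_id": [f"P{i}" for i in range(4)],
                            "discharged_alive_day": [None] * 4})
        # two patients pass variant c only (lactate 1.8), two pass nothing
        rows = []
        for i in range(2):
            rows += [(f"P{i}", 3, "blood_culture", "blood_culture", np.nan),
                     (f"P{i}", 4, "lab", "lactate", 1.8)]
            rows += [(f"P{i}", d, "antimicrobial", "antimicrobial", np.nan)
                     for d in range(3, 8)]
        ev = pd.DataFrame(rows, columns=["patient_id", "day", "event_type",
                                         "name", "value"])
        rep = reclassify_liberalized(enc, ev).set_index("variant_id")
        assert rep.loc["c", "n_reclassified"] == 2
        assert rep.loc["c", "pct"] == 50.0
        assert rep.loc["a", "n_reclassified"] == 0
        assert rep.loc["j", "n_reclassified"] == 2

    def test_empty_variant_list(self):
        enc = pd.DataFrame({"patient_id": ["P0"], "discharged_alive_day": [None]})
        ev = toy_events([])
        assert len(reclassify_liberalized(enc, ev, [])) == 0


class TestStandardizedDifference:
    def test_identical_groups_zero(self):
        d, cls = standardized_difference((0.5, 1.0), (0.5, 1.0), "continuous")
        assert d == 0.0 and cls == "negligible"

    def test_published_binary_rows(self):
        """Cohort ASE rates 787/3660 vs 576/3012 give d = -0.06; female
        rates 1315/3660 vs 956/3012 give |d| = 0.09 (both negligible)."""
        d, cls = standardized_difference((787, 3660), (576, 3012), "binary")
        assert round(d, 2) == -0.06 and cls == "negligible"
        d, cls = standardized_difference((1315, 3660), (956, 3012), "binary")
        assert round(abs(d), 2) == 0.09 and cls == "negligible"

    def test_effect_classes(self):
        assert standardized_difference((0.0, 1.0), (0.3, 1.0), "continuous")[1] == "small"
        assert standardized_difference((0.0, 1.0), (0.6, 1.0), "continuous")[1] == "medium"
        assert standardized_difference((0.0, 1.0), (1.5, 1.0), "continuous")[1] == "large"

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ZeroDivisionError):
            standardized_difference((1.0, 0.0), (2.0, 0.0), "continuous")
        with pytest.raises(ZeroDivisionError):
            standardized_difference(0.0, 0.0, "binary")
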