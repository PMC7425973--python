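"""Phase classification, eligibility screening and treatment typing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasecost.errors import DataError
from phasecost.months import month_index, month_label
from phasecost.phases import (
    classify_phases,
    detect_recurrence,
    find_index_month,
    assign_treatment_type,
    build_case_register,
)
from phasecost.taxonomy import MODALITIES, treatment_type_for

from conftest import make_timeline


M = month_index("2013-05")  # reference index month used throughout


@given(st.integers(min_value=1900 * 12, max_value=2100 * 12))
@settings(derandomize=True)
def test_month_roundtrip(idx):
    assert month_index(month_label(idx)) == idx


class TestFindIndexMonth:
    def test_basic_index_with_clean_lookback(self):
        tl = make_timeline("2012-01", 24, dx_hcc=["2013-05", "2013-06"])
        assert find_index_month(tl, "1943-05") == M

    def test_other_cancer_in_lookback_disqualifies(self):
        tl = make_timeline("2012-01", 24, dx_hcc=["2013-05"],
                           dx_other_cancer=["2013-01"])
        assert find_index_month(tl, "1943-05") is None

    def test_under_20_at_diagnosis_ineligible(self):
        tl = make_timeline("2012-01", 24, dx_hcc=["2013-05"])
        assert find_index_month(tl, "1994-01") is None

    def test_short_observation_before_first_flag_ineligible(self):
        tl = make_timeline("2013-01", 12, dx_hcc=["2013-05"])
        assert find_index_month(tl, "1943-05") is None

    def test_exactly_12_observed_clean_months_qualify(self):
        tl = make_timeline("2012-05", 14, dx_hcc=["2013-05"])
        assert find_index_month(tl, "1943-05") == M

    def test_unsorted_months_rejected(self):
        tl = make_timeline("2012-01", 24, dx_hcc=["2013-05"])
        with pytest.raises(DataError):
            find_index_month(tl.iloc[::-1], "1943-05")

    def test_duplicate_months_rejected(self):
        tl = make_timeline("2012-01", 24, dx_hcc=["2013-05"])
        import pandas as pd
        with pytest.raises(DataError):
            find_index_month(pd.concat([tl, tl.iloc[[3]]]).sort_values("month"),
                             "1943-05")


class TestRecurrence:
    def test_seven_month_gap_then_new_diagnosis_is_recurrence(self):
        tl = make_timeline("2013-01", 30, dx_hcc=["2013-05", "2014-11"],
                           tx={"tace": ["2013-05", "2014-03"]})
        assert detect_recurrence(tl, "2013-05") is True

    def test_continuous_treatment_is_not_recurrence(self):
        months = [f"2013-{m:02d}" for m in range(5, 13)] + [
            f"2014-{m:02d}" for m in range(1, 13)
        ]
        tl = make_timeline("2013-01", 30, dx_hcc=months, tx={"tace": months})
        assert detect_recurrence(tl, "2013-05") is False

    def test_six_month_gap_is_below_threshold(self):
        # last therapy 2014-03, six treatment-free months, diagnosis 2014-10
        tl = make_timeline("2013-01", 30, dx_hcc=["2013-05", "2014-10"],
                           tx={"tace": ["2013-05", "2014-03"]})
        assert detect_recurrence(tl, "2013-05") is False

    def test_no_treatment_at_all_is_not_recurrence(self):
        tl = make_timeline("2013-01", 30, dx_hcc=["2013-05", "2014-11"])
        assert detect_recurrence(tl, "2013-05") is False


class TestClassifyPhases:
    def test_death_during_index_month(self):
        pm = classify_phases(M, M, first_month=M - 14)
        assert pm.months("initial") == [M - 1]
        assert pm.months("terminal") == [M]
        assert pm.months("continuing") == []

    def test_death_one_month_after_index(self):
        pm = classify_phases(M, M + 1)
        assert pm.months("initial") == [M - 1, M]
        assert pm.months("terminal") == [M + 1]
        assert pm.months("continuing") == []

    def test_death_five_months_after_index(self):
        pm = classify_phases(M, M + 5)
        assert pm.months("initial") == [M - 1, M, M + 1]
        assert pm.months("terminal") == list(range(M + 2, M + 6))
        assert pm.months("continuing") == []

    def test_standard_pattern_two_years_out(self):
        pm = classify_phases(M, M + 24)
        assert pm.months("initial") == [M - 1, M, M + 1]
        assert pm.months("terminal") == list(range(M + 19, M + 25))
        assert pm.months("continuing") == list(range(M + 2, M + 19))

    def test_censored_case_has_no_terminal(self):
        pm = classify_phases(M, None, last_month=M + 10)
        assert pm.months("terminal") == []
        assert pm.months("continuing") == list(range(M + 2, M + 11))

    def test_censored_initial_clipped_to_observation(self):
        pm = classify_phases(M, None, last_month=M)
        assert pm.months("initial") == [M - 1, M]
        assert pm.months("continuing") == []

    def test_pre_months_labeled(self):
        pm = classify_phases(M, M + 24, first_month=M - 14)
        assert pm.months("pre") == list(range(M - 14, M - 1))

    def test_death_before_index_rejected(self):
        with pytest.raises(DataError):
            classify_phases(M, M - 1)

    @pytest.mark.parametrize("offset", range(0, 61))
    def test_partition_is_exhaustive_and_disjoint(self, offset):
        """Every month from index-1 through death belongs to exactly one phase."""
        pm = classify_phases(M, M + offset)
        labels = {}
        for phase in ("initial", "continuing", "terminal"):
            for m in pm.months(phase):
                assert m not in labels, f"month {m} labeled twice"
                labels[m] = phase
        assert sorted(labels) == list(range(M - 1, M + offset + 1))
        # the death month is always terminal
        assert labels[M + offset] == "terminal"
        # block lengths per the window definitions
        assert len(pm.months("initial")) <= 3
        if offset >= 2:
            assert len(pm.months("terminal")) == min(6, offset - 1)

    @given(st.integers(min_value=0, max_value=600))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_partition_property_arbitrary_offsets(self, offset):
        pm = classify_phases(M, M + offset)
        all_months = sorted(
            m for p in ("initial", "continuing", "terminal") for m in pm.months(p)
        )
        assert all_months == list(range(M - 1, M + offset + 1))


class TestTreatmentType:
    @pytest.mark.parametrize(
        "mods,expected",
        [
            ({"resection"}, "Surgical resection only"),
            ({"resection", "lrt"}, "Surgical resection + LRT"),
            ({"resection", "tace", "tae"}, "Surgical resection + TACE/TAE"),
            ({"resection", "radiotherapy"}, "Surgical resection + others"),
            ({"lrt"}, "LRT only"),
            ({"lrt", "tae"}, "LRT + TACE/TAE"),
            ({"lrt", "chemo"}, "LRT + chemotherapy"),
            ({"lrt", "sorafenib"}, "LRT + others"),
            ({"tace"}, "TACE only"),
            ({"tace", "chemo"}, "TACE + chemotherapy"),
            ({"tace", "chemo", "sorafenib"}, "TACE + chemotherapy + sorafenib"),
            ({"tae"}, "TAE only"),
            ({"tae", "chemo"}, "TAE + chemotherapy"),
            ({"sorafenib"}, "Sorafenib only"),
            ({"sorafenib", "chemo"}, "Sorafenib + chemotherapy"),
            ({"chemo"}, "Others"),
            ({"radiotherapy"}, "Others"),
            ({"tace", "sorafenib"}, "Others"),
        ],
    )
    def test_named_combinations(self, mods, expected):
        assert treatment_type_for(frozenset(mods)) == expected

    def test_total_and_deterministic_over_all_subsets(self):
        """Every one of the 2^7 modality sets maps to exactly one category."""
        from phasecost.taxonomy import TREATMENT_TYPES
        for r in range(1, len(MODALITIES) + 1):
            for combo in itertools.combinations(MODALITIES, r):
                label = treatment_type_for(frozenset(combo))
                assert label in TREATMENT_TYPES
                assert treatment_type_for(frozenset(combo)) == label

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError):
            treatment_type_for(frozenset({"leeches"}))

    def test_assignment_window_and_no_treatment(self):
        tl = make_timeline("2012-01", 24, dx_hcc=["2013-05"],
                           tx={"resection": ["2013-05"]})
        assert assign_treatment_type(tl, "2013-05", "2013-12") == (
            "Surgical resection only"
        )
        bare = make_timeline("2012-01", 24, dx_hcc=["2013-05"])
        assert assign_treatment_type(bare, "2013-05", "2013-12") is None


class TestCaseRegister:
    def test_register_on_synthetic_panel(self):
        from phasecost.scenarios import null_config
        from phasecost.simulate import generate_population

        claims, demo, truth = generate_population(null_config(seed=3))
        register, phase_maps = build_case_register(claims, demo)
        truth = truth.set_index("patient_id")
        # every eligible case's index month matches the injected truth
        for _, row in register[register["eligible"]].iterrows():
            t = truth.loc[row["patient_id"]]
            assert month_label(int(row["index_month"])) == t["hcc_index_month"]
            assert row["patient_id"] in phase_maps
        # death-cohort membership requires an observed death
        dead = register["death_month"].notna()
        assert (register.loc[register["in_death_cohort"], "death_month"].notna()).all()
        assert set(register.loc[~dead, "in_death_cohort"]) <= {False}
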