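"""Exact matching: keys, window expansion, without-replacement selection."""

import numpy as np
import pandas as pd
import pytest

from phasecost.config import AGE_BANDS, age_band_of
from phasecost.errors import DataError
from phasecost.matching import (
    ExactMatcher,
    MatchKey,
    build_match_key,
    condition_onsets,
    match_death,
    match_incident,
)
from phasecost.months import NEVER, month_index
from phasecost.taxonomy import CCI_COLUMNS


def test_age_bands_against_interval_oracle():
    """Band label for every adult age agrees with an independent digitize oracle."""
    edges = np.arange(20, 100, 5)
    for age in range(20, 101):
        k = int(np.digitize(age, edges)) - 1
        expected = "95+" if age >= 95 else f"{edges[k]}-{edges[k] + 4}"
        assert age_band_of(age) == expected
    assert age_band_of(20) == "20-24"
    with pytest.raises(Exception):
        age_band_of(19)


class TestMatchKey:
    def test_key_fields(self):
        flags = [0] * 15
        flags[8] = 1  # mild liver disease
        key = build_match_key("F", "1941-03", "2013-05", flags)
        assert key == MatchKey("F", "70-74", tuple(flags))

    def test_identical_patients_get_equal_keys(self):
        flags = [0, 1] * 7 + [0]
        a = build_match_key("M", "1950-01", "2015-06", flags)
        b = build_match_key("M", "1950-01", "2015-06", list(flags))
        assert a == b

    def test_missing_fields_rejected(self):
        with pytest.raises(DataError):
            build_match_key("X", "1950-01", "2015-06", [0] * 15)
        with pytest.raises(DataError):
            build_match_key("F", "1950-01", "2015-06", [0] * 14)


def _cases(rows):
    df = pd.DataFrame(rows)
    for col in CCI_COLUMNS:
        if col not in df.columns:
            df[col] = 0
    return df


def _controls(rows):
    df = pd.DataFrame(rows)
    for col in CCI_COLUMNS:
        if col not in df.columns:
            df[col] = NEVER
    if "death_month" not in df.columns:
        df["death_month"] = NEVER
    return df


M = month_index("2013-05")
BIRTH = month_index("1941-03")  # age 72 at M (band stable across small offsets)


class TestIncidentMatching:
    def test_exact_stratum_control_in_index_month(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([{"patient_id": "K1", "sex": "F", "birth_month": BIRTH}])
        util = {M: np.array([0])}
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, util)
        assert len(m.pairs_) == 1
        assert m.pairs_.iloc[0]["control_id"] == "K1"
        assert m.pairs_.iloc[0]["anchor_offset"] == 0

    def test_window_expansion_to_plus_three(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([{"patient_id": "K1", "sex": "F", "birth_month": BIRTH}])
        util = {M + 3: np.array([0])}
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, util)
        assert m.pairs_.iloc[0]["anchor_offset"] == 3

    def test_equidistant_tie_prefers_earlier_month(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([
            {"patient_id": "K1", "sex": "F", "birth_month": BIRTH},
            {"patient_id": "K2", "sex": "F", "birth_month": BIRTH},
        ])
        util = {M - 2: np.array([0]), M + 2: np.array([1])}
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, util)
        assert m.pairs_.iloc[0]["anchor_offset"] == -2

    def test_beyond_twelve_months_unmatched(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([{"patient_id": "K1", "sex": "F", "birth_month": BIRTH}])
        util = {M + 13: np.array([0])}
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, util)
        assert len(m.pairs_) == 0
        assert list(m.unmatched_["case_id"]) == ["C1"]

    def test_stratum_mismatch_unmatched(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([
            {"patient_id": "K1", "sex": "M", "birth_month": BIRTH},   # wrong sex
            {"patient_id": "K2", "sex": "F", "birth_month": BIRTH - 120},  # wrong band
        ])
        util = {M: np.array([0, 1])}
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, util)
        assert len(m.pairs_) == 0

    def test_without_replacement_two_cases_one_control(self):
        cases = _cases([
            {"patient_id": "C1", "anchor_month": M, "sex": "F", "birth_month": BIRTH},
            {"patient_id": "C2", "anchor_month": M, "sex": "F", "birth_month": BIRTH},
        ])
        controls = _controls([{"patient_id": "K1", "sex": "F", "birth_month": BIRTH}])
        util = {M: np.array([0])}
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, util)
        assert len(m.pairs_) == 1 and len(m.unmatched_) == 1
        # ascending patient-id processing makes the matched case deterministic
        assert m.pairs_.iloc[0]["case_id"] == "C1"
        assert m.unmatched_.iloc[0]["case_id"] == "C2"
        # same result regardless of the order rows arrive in
        m2 = ExactMatcher("incident", random_state=0).fit(
            cases.iloc[::-1], controls, util
        )
        pd.testing.assert_frame_equal(m.pairs_, m2.pairs_)

    def test_empty_pool_reports_all_unmatched(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([]) if False else _controls(
            [{"patient_id": "K1", "sex": "F", "birth_month": BIRTH}]
        ).iloc[:0]
        m = ExactMatcher("incident", random_state=0).fit(cases, controls, {})
        assert len(m.pairs_) == 0 and len(m.unmatched_) == 1


class TestDeathMatching:
    def test_same_death_month_and_key_matched(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([{"patient_id": "K1", "sex": "F",
                               "birth_month": BIRTH, "death_month": M}])
        m = ExactMatcher("death", random_state=0).fit(cases, controls)
        assert len(m.pairs_) == 1
        assert m.pairs_.iloc[0]["anchor_offset"] == 0

    def test_death_one_month_later_is_not_matched(self):
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                         "birth_month": BIRTH}])
        controls = _controls([{"patient_id": "K1", "sex": "F",
                               "birth_month": BIRTH, "death_month": M + 1}])
        m = ExactMatcher("death", random_state=0).fit(cases, controls)
        assert len(m.pairs_) == 0

    def test_same_seed_reproduces_pairs(self):
        controls = _controls([
            {"patient_id": f"K{i}", "sex": "F", "birth_month": BIRTH,
             "death_month": M} for i in range(10)
        ])
        cases = _cases([{"patient_id": "C1", "anchor_month": M, "sex": "F",
                        "birth_month": BIRTH}])
        a = ExactMatcher("death", random_state=42).fit(cases, controls).pairs_
        b = ExactMatcher("death", random_state=42).fit(cases, controls).pairs_
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def panel():
    from phasecost.scenarios import recovery_config
    from phasecost.simulate import generate_population
    from phasecost.phases import build_case_register

    cfg = recovery_config(seed=2, n_patients=2500)
    claims, demo, _ = generate_population(cfg)
    register, _ = build_case_register(claims, demo)
    return cfg, claims, demo, register


class TestEndToEndMatching:
    def test_matched_groups_have_identical_keys(self, panel):
        """Case and control agree exactly on sex, age band and all 15 flags."""
        _, claims, demo, register = panel
        pairs, _ = match_incident(register, claims, demo, seed=0)
        assert len(pairs) > 50
        onsets = condition_onsets(claims)
        demo_i = demo.set_index("patient_id")
        reg_i = register.set_index("patient_id")
        def key_at(pid, anchor):
            flags = (onsets.loc[pid].to_numpy() <= anchor).astype(int)
            return build_match_key(
                demo_i.loc[pid, "sex"], demo_i.loc[pid, "birth_month"], anchor, flags
            )

        for _, p in pairs.sample(min(40, len(pairs)), random_state=0).iterrows():
            anchor = int(reg_i.loc[p["case_id"], "index_month"])
            ctrl_anchor = anchor + int(p["anchor_offset"])
            assert key_at(p["case_id"], anchor) == key_at(p["control_id"], ctrl_anchor)

    def test_no_control_reused_and_controls_hcc_free(self, panel):
        _, claims, demo, register = panel
        pairs_i, unmatched_i = match_incident(register, claims, demo, seed=0)
        assert pairs_i["control_id"].is_unique
        hcc_ids = set(claims.loc[claims["dx_hcc"] == 1, "patient_id"])
        assert not (set(pairs_i["control_id"]) & hcc_ids)
        # reconciliation: every incident case is matched or reported unmatched
        n_cases = int(register["in_incident_cohort"].sum())
        assert len(pairs_i) + len(unmatched_i) == n_cases

    def test_match_rate_monotone_in_pool_size(self, panel):
        """Adding controls never decreases the number of matched cases."""
        _, claims, demo, register = panel
        controls = demo[~demo["patient_id"].isin(
            claims.loc[claims["dx_hcc"] == 1, "patient_id"])]["patient_id"].to_numpy()
        rates = []
        for frac in (0.3, 0.6, 1.0):
            keep = set(controls[: int(len(controls) * frac)]) | set(
                register["patient_id"]
            )
            demo_sub = demo[demo["patient_id"].isin(keep)]
            claims_sub = claims[claims["patient_id"].isin(keep)]
            pairs, _ = match_incident(register, claims_sub, demo_sub, seed=0)
            rates.append(len(pairs))
        assert rates == sorted(rates)
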