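"""Exact case-control matching without replacement.

Each hepatocellular-carcinoma case is matched to exactly one control with an
identical key — sex, 5-year age band, and the 15 Charlson condition flags —
anchored on a calendar month:

* **incident cohort** — the anchor is the case's index month and the control
  must have received care (any utilization) in that month; if no control
  exists the window expands month by month up to one year, trying the earlier
  of two equidistant months first;
* **death cohort** — the anchor is the case's death month and the control
  must have died in exactly that month (no expansion).

Controls have no HCC history, are drawn uniformly at random with a seeded
generator, and are removed from the pool once matched.  Cases are processed
in ascending patient-id order.  Unmatched cases are reported, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import age_band_of
from .errors import DataError
from .months import NEVER, month_index, month_index_series, age_in_years
from .taxonomy import CCI_COLUMNS

MAX_OFFSET_MONTHS = 12


class MatchKey(NamedTuple):
    """Exact-matching stratum: sex, 5-year age band, 15 condition flags."""

    sex: str
    age_band: str
    cci_flags: Tuple[int, ...]


def build_match_key(sex: str, birth_month, anchor_month, cci_flags) -> MatchKey:
    """Key for one patient at an anchor month (age in completed years there)."""
    if sex not in ("F", "M"):
        raise DataError(f"sex must be 'F' or 'M', got {sex!r}")
    if birth_month is None or (isinstance(birth_month, float) and np.isnan(birth_month)):
        raise DataError("missing birth month")
    flags = tuple(int(bool(f)) for f in cci_flags)
    if len(flags) != 15:
        raise DataError(f"expected 15 condition flags, got {len(flags)}")
    age = age_in_years(month_index(anchor_month), month_index(birth_month))
    return MatchKey(sex=sex, age_band=age_band_of(age), cci_flags=flags)


def _offsets(max_offset: int):
    """0, -1, +1, -2, +2, ...: nearest month first, earlier month on ties."""
    yield 0
    for k in range(1, max_offset + 1):
        yield -k
        yield k


def condition_onsets(claims: pd.DataFrame) -> pd.DataFrame:
    """First month each Charlson flag appears, per patient (NEVER if absent).

    Condition flags in claims are onset-only (no remission), so the flag state
    as of any month — equivalently over any window ending at that month — is
    ``first_flag_month <= month``.
    """
    codes, uniques = pd.factorize(claims["patient_id"])
    m = month_index_series(claims["month"]).to_numpy()
    out = pd.DataFrame(index=pd.Index(uniques, name="patient_id"))
    for col in CCI_COLUMNS:
        mask = claims[col].to_numpy().astype(bool)
        first = np.full(len(uniques), NEVER, dtype=np.int64)
        np.minimum.at(first, codes[mask], m[mask])
        out[col] = first
    return out


class ExactMatcher(BaseEstimator):
    """Exact matching of cases to never-HCC controls, without replacement.

    Parameters
    ----------
    cohort : {'incident', 'death'}
        Incident matching anchors on the index month with window expansion up
        to ``max_offset_months``; death matching requires the identical death
        month with no expansion.
    max_offset_months : int
        Maximum anchor-window expansion (incident cohort only).
    random_state : int or None
        Seed for the uniform draw among tied candidate controls.

    Attributes
    ----------
    pairs_ : DataFrame with columns cohort, case_id, control_id, anchor_offset.
    unmatched_ : DataFrame with columns case_id, reason.
    n_matched_ : int
    """

    def __init__(self, cohort: str = "incident", max_offset_months: int = MAX_OFFSET_MONTHS,
                 random_state: Optional[int] = None):
        self.cohort = cohort
        self.max_offset_months = max_offset_months
        self.random_state = random_state

    def fit(self, cases: pd.DataFrame, controls: pd.DataFrame,
            control_util: Optional[Dict[int, np.ndarray]] = None) -> "ExactMatcher":
        """Match each case to at most one control.

        ``cases``: one row per case with ``patient_id``, ``anchor_month``
        (int month index), ``sex``, ``birth_month`` (int) and the 15
        ``cci_*`` flag columns evaluated at the anchor.

        ``controls``: one row per candidate with ``patient_id``, ``sex``,
        ``birth_month`` (int), ``death_month`` (int or NEVER) and the 15
        ``cci_*`` columns holding each condition's *onset month* (NEVER if
        never flagged); the flag state at month ``m`` is ``onset <= m``.

        ``control_util``: for the incident cohort, a mapping month ->
        array of control row positions with utilization that month.
        """
        if self.cohort not in ("incident", "death"):
            raise ValueError(f"cohort must be 'incident' or 'death', got {self.cohort!r}")
        rng = np.random.default_rng(self.random_state)

        c_sex = controls["sex"].to_numpy()
        c_birth = controls["birth_month"].to_numpy(np.int64)
        c_onset = controls[list(CCI_COLUMNS)].to_numpy(np.int64)
        c_ids = controls["patient_id"].to_numpy()
        n_controls = len(controls)
        used = np.zeros(n_controls, dtype=bool)

        if self.cohort == "death":
            c_death = controls["death_month"].to_numpy(np.int64)
            death_index: Dict[int, np.ndarray] = {}
            for m in np.unique(c_death[c_death != NEVER]):
                death_index[int(m)] = np.flatnonzero(c_death == m)
        elif control_util is None:
            raise ValueError("control_util is required for incident matching")

        pairs = []
        unmatched = []
        cases = cases.sort_values("patient_id")
        case_flags = cases[list(CCI_COLUMNS)].to_numpy()

        for row_i, (_, case) in enumerate(cases.iterrows()):
            anchor = int(case["anchor_month"])
            case_band = age_band_of(age_in_years(anchor, int(case["birth_month"])))
            flags = case_flags[row_i].astype(np.int64)
            offsets = [0] if self.cohort == "death" else _offsets(self.max_offset_months)
            pick = None
            pick_offset = 0
            for off in offsets:
                m = anchor + off
                if self.cohort == "death":
                    cand = death_index.get(m)
                else:
                    cand = control_util.get(m)
                if cand is None or len(cand) == 0:
                    continue
                cand = cand[~used[cand]]
                if len(cand) == 0:
                    continue
                ok = c_sex[cand] == case["sex"]
                ages = (m - c_birth[cand]) // 12
                ok &= ages >= 20
                cand = cand[ok]
                if len(cand) == 0:
                    continue
                cand_bands = np.array(
                    [age_band_of(a) for a in (m - c_birth[cand]) // 12]
                )
                cand = cand[cand_bands == case_band]
                if len(cand) == 0:
                    continue
                same = ((c_onset[cand] <= m).astype(np.int64) == flags[None, :]).all(axis=1)
                cand = cand[same]
                if len(cand) == 0:
                    continue
                pick = int(rng.choice(cand))
                pick_offset = off
                break
            if pick is None:
                unmatched.append({"case_id": case["patient_id"],
                                  "reason": "no_eligible_control"})
            else:
                used[pick] = True
                pairs.append(
                    {
                        "cohort": self.cohort,
                        "case_id": case["patient_id"],
                        "control_id": c_ids[pick],
                        "anchor_offset": pick_offset,
                    }
                )
        self.pairs_ = pd.DataFrame(
            pairs, columns=["cohort", "case_id", "control_id", "anchor_offset"]
        )
        self.unmatched_ = pd.DataFrame(unmatched, columns=["case_id", "reason"])
        self.n_matched_ = len(self.pairs_)
        return self


def _control_pool(claims: pd.DataFrame, demographics: pd.DataFrame,
                  onsets: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Candidate controls: patients with no HCC diagnosis flag, ever."""
    hcc_ids = set(claims.loc[claims["dx_hcc"].astype(bool), "patient_id"].unique())
    pool = demographics[~demographics["patient_id"].isin(hcc_ids)].copy()
    if onsets is None:
        onsets = condition_onsets(claims)
    pool["birth_month"] = month_index_series(pool["birth_month"])
    death = pool["death_month"].astype(str)
    pool["death_month"] = [
        month_index(d) if d not in ("", "nan", "None", "NaT") else NEVER for d in death
    ]
    pool = pool.merge(onsets.reindex(pool["patient_id"]).fillna(NEVER).astype(np.int64),
                      left_on="patient_id", right_index=True, how="left")
    return pool.reset_index(drop=True)


def _case_frame(register: pd.DataFrame, demographics: pd.DataFrame,
                claims: pd.DataFrame, anchor_col: str,
                onsets: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    demo = demographics.set_index("patient_id")
    if onsets is None:
        onsets = condition_onsets(claims)
    cases = register.copy()
    cases["anchor_month"] = cases[anchor_col].astype(np.int64)
    cases["sex"] = demo.loc[cases["patient_id"], "sex"].to_numpy()
    cases["birth_month"] = month_index_series(
        demo.loc[cases["patient_id"], "birth_month"]
    ).to_numpy()
    case_onsets = onsets.reindex(cases["patient_id"]).fillna(NEVER).to_numpy(np.int64)
    for j, col in enumerate(CCI_COLUMNS):
        cases[col] = (case_onsets[:, j] <= cases["anchor_month"].to_numpy()).astype(int)
    return cases[["patient_id", "anchor_month", "sex", "birth_month", *CCI_COLUMNS]]


def utilization_index(claims: pd.DataFrame, pool: pd.DataFrame) -> Dict[int, np.ndarray]:
    """Map month -> positions (into ``pool``) of controls with utilization."""
    codes, uniques = pd.factorize(claims["patient_id"])
    pos_of = {pid: i for i, pid in enumerate(pool["patient_id"])}
    code_to_pos = np.array([pos_of.get(pid, -1) for pid in uniques], dtype=np.int64)
    keep = (claims["expenditure_yen"].to_numpy() > 0) & (code_to_pos[codes] >= 0)
    m = month_index_series(claims["month"]).to_numpy()[keep]
    p = code_to_pos[codes[keep]]
    out: Dict[int, np.ndarray] = {}
    order = np.argsort(m, kind="stable")
    m, p = m[order], p[order]
    bounds = np.flatnonzero(np.diff(m)) + 1
    for chunk_m, chunk_p in zip(np.split(m, bounds), np.split(p, bounds)):
        if len(chunk_m):
            out[int(chunk_m[0])] = np.unique(chunk_p)
    return out


def match_incident(register: pd.DataFrame, claims: pd.DataFrame,
                   demographics: pd.DataFrame, seed: int,
                   max_offset: int = MAX_OFFSET_MONTHS,
                   onsets: Optional[pd.DataFrame] = None
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Match incident-cohort cases on the index month with window expansion."""
    cases = register[register["in_incident_cohort"]]
    case_frame = _case_frame(cases, demographics, claims, "index_month", onsets)
    pool = _control_pool(claims, demographics, onsets)
    util = utilization_index(claims, pool)
    matcher = ExactMatcher("incident", max_offset, random_state=seed)
    matcher.fit(case_frame, pool, control_util=util)
    return matcher.pairs_, matcher.unmatched_


def match_death(register: pd.DataFrame, claims: pd.DataFrame,
                demographics: pd.DataFrame, seed: int,
                onsets: Optional[pd.DataFrame] = None
                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Match death-cohort cases on the exact death month (no expansion)."""
    cases = register[register["in_death_cohort"]]
    case_frame = _case_frame(cases, demographics, claims, "death_month", onsets)
    pool = _control_pool(claims, demographics, onsets)
    matcher = ExactMatcher("death", random_state=seed)
    matcher.fit(case_frame, pool)
    return matcher.pairs_, matcher.unmatched_
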