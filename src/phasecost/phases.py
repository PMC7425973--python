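"""Case identification and phase-of-care classification.

Each eligible hepatocellular-carcinoma (HCC) case's observed months are
partitioned into phases of care:

* ``initial`` — the 3-month window around the index month (the month before,
  the index month itself, and the month after);
* ``terminal`` — the 6-month window ending at (and including) the death month;
* ``continuing`` — the contiguous block strictly between the two;
* ``pre`` — everything before the initial phase.

Deaths close to diagnosis collapse the pattern: death in the index month
leaves ``initial = {index-1}`` and ``terminal = {index}``; death one month
after the index leaves ``initial = {index-1, index}`` and
``terminal = {index+1}``; death within 7 months of the index keeps the full
initial window and labels everything from ``index+2`` to death as terminal.
In all of these there is no continuing phase.

Eligibility requires age >= 20 at the index month and a 12-month observed
cancer-free lookback; recurrent HCC (a new diagnosis after >= 7 consecutive
months without any anticancer therapy following the initial treatment) is
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .months import month_index, month_index_series, month_labels, age_in_years
from .taxonomy import CCI_COLUMNS, MODALITIES, TX_COLUMNS, treatment_type_for

PHASE_LABELS = ("pre", "initial", "continuing", "terminal", "excluded")

LOOKBACK_MONTHS = 12
MIN_AGE_YEARS = 20
RECURRENCE_GAP_MONTHS = 7
TERMINAL_WINDOW = 6
#: Largest death-minus-index offset treated as "death within 7 months of the
#: index" (no continuing phase).
EXCEPTION_MAX_OFFSET = 7


@dataclass
class PhaseMap:
    """Per-patient assignment of each observed month to a phase label."""

    patient_id: str
    assignments: Dict[int, str] = field(default_factory=dict)

    def months(self, phase: str) -> List[int]:
        """Sorted month indices assigned to ``phase``."""
        return sorted(m for m, p in self.assignments.items() if p == phase)

    def to_frame(self) -> pd.DataFrame:
        months = sorted(self.assignments)
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "month": month_labels(months),
                "phase": [self.assignments[m] for m in months],
            }
        )


def classify_phases(
    index_month,
    death_month=None,
    last_month=None,
    first_month=None,
    patient_id: str = "",
) -> PhaseMap:
    """Partition a case's months into pre / initial / continuing / terminal.

    ``last_month`` is the last observed month (required when no death is
    observed); ``first_month`` is the first observed month and bounds the
    ``pre`` block (defaults to ``index_month - 1``).  Months are ``YYYY-MM``
    strings or month indices.
    """
    index = month_index(index_month)
    death = None if death_month is None else month_index(death_month)
    if death is not None and death < index:
        raise DataError(
            f"death month {death_month!r} precedes index month {index_month!r}"
        )
    if death is None:
        if last_month is None:
            raise DataError("last_month is required when no death is observed")
        end = month_index(last_month)
        if end < index:
            raise DataError("last observed month precedes the index month")
    else:
        end = death

    assignments: Dict[int, str] = {}
    if death is not None and death == index:
        initial = [index - 1]
        terminal = [index]
        continuing: List[int] = []
    elif death is not None and death == index + 1:
        initial = [index - 1, index]
        terminal = [index + 1]
        continuing = []
    elif death is not None and death - index <= EXCEPTION_MAX_OFFSET:
        initial = [index - 1, index, index + 1]
        terminal = list(range(index + 2, death + 1))
        continuing = []
    else:
        if death is not None:
            initial = [index - 1, index, index + 1]
            terminal = list(range(death - TERMINAL_WINDOW + 1, death + 1))
            continuing = list(range(index + 2, death - TERMINAL_WINDOW + 1))
        else:
            # censored: phases cannot extend past the last observed month
            initial = [m for m in (index - 1, index, index + 1) if m <= end]
            terminal = []
            continuing = list(range(index + 2, end + 1))

    first = index - 1 if first_month is None else month_index(first_month)
    for m in range(first, min(initial) if initial else index):
        assignments[m] = "pre"
    for m in initial:
        if m >= first:
            assignments[m] = "initial"
    for m in continuing:
        assignments[m] = "continuing"
    for m in terminal:
        assignments[m] = "terminal"
    return PhaseMap(patient_id=patient_id, assignments=assignments)


def _check_timeline(months: np.ndarray) -> None:
    if len(months) == 0:
        raise DataError("empty timeline")
    diffs = np.diff(months)
    if np.any(diffs == 0):
        raise DataError("duplicated months in timeline")
    if np.any(diffs < 0):
        raise DataError("timeline months are not sorted")


def find_index_month(
    timeline: pd.DataFrame,
    birth_month,
    lookback: int = LOOKBACK_MONTHS,
    min_age: int = MIN_AGE_YEARS,
) -> Optional[int]:
    """First qualifying HCC index month for one patient, or ``None``.

    The index month is the first month flagged ``dx_hcc`` whose preceding
    ``lookback`` *observed* months carry no cancer diagnosis flag (HCC or
    other).  Patients younger than ``min_age`` at that month are ineligible,
    as are patients observed for fewer than ``lookback`` months beforehand.
    """
    months = month_index_series(timeline["month"]).to_numpy()
    _check_timeline(months)
    dx_hcc = timeline["dx_hcc"].to_numpy().astype(bool)
    dx_any = dx_hcc | timeline["dx_other_cancer"].to_numpy().astype(bool)
    birth = month_index(birth_month)
    for pos in np.flatnonzero(dx_hcc):
        if pos < lookback:
            continue
        if dx_any[pos - lookback : pos].any():
            continue
        month = int(months[pos])
        if age_in_years(month, birth) < min_age:
            return None
        return month
    return None


def detect_recurrence(
    timeline: pd.DataFrame,
    index_month,
    gap_months: int = RECURRENCE_GAP_MONTHS,
) -> bool:
    """Flag recurrent HCC: a diagnosis month preceded by a >= 7-month therapy gap.

    The gap is counted after the last month of the initial treatment (the last
    treated month within the 3-month initial window, or the first treated
    month overall if treatment started later).  Returns ``False`` for
    patients with no anticancer therapy at all (they are excluded upstream
    for lacking a treatment type).
    """
    months = month_index_series(timeline["month"]).to_numpy()
    _check_timeline(months)
    index = month_index(index_month)
    tx_any = timeline[list(TX_COLUMNS)].to_numpy().astype(bool).any(axis=1)
    dx_hcc = timeline["dx_hcc"].to_numpy().astype(bool)

    tx_months = months[tx_any]
    if len(tx_months) == 0:
        return False
    in_initial = tx_months[(tx_months >= index - 1) & (tx_months <= index + 1)]
    treatment_start = int(in_initial.max()) if len(in_initial) else int(tx_months.min())

    tx_set = set(tx_months.tolist())
    for pos in np.flatnonzero(dx_hcc):
        m = int(months[pos])
        if m <= treatment_start:
            continue
        gap = 0
        probe = m - 1
        while probe > treatment_start and probe not in tx_set and gap < gap_months:
            gap += 1
            probe -= 1
        if gap >= gap_months:
            return True
    return False


def assign_treatment_type(
    timeline: pd.DataFrame,
    index_month,
    end_month,
) -> Optional[str]:
    """Treatment-type label from modalities flagged in ``[index-1, end]``.

    Returns ``None`` when no anticancer modality is observed in the window
    (such cases are excluded: only treated patients are analysed).
    """
    months = month_index_series(timeline["month"]).to_numpy()
    _check_timeline(months)
    index = month_index(index_month)
    end = month_index(end_month)
    window = (months >= index - 1) & (months <= end)
    mods = set()
    tx = timeline[list(TX_COLUMNS)].to_numpy().astype(bool)
    for j, mod in enumerate(MODALITIES):
        if tx[window, j].any():
            mods.add(mod)
    if not mods:
        return None
    return treatment_type_for(frozenset(mods))


def build_case_register(
    claims: pd.DataFrame,
    demographics: pd.DataFrame,
    lookback: int = LOOKBACK_MONTHS,
    min_age: int = MIN_AGE_YEARS,
) -> Tuple[pd.DataFrame, Dict[str, PhaseMap]]:
    """Screen every HCC-flagged patient and build the case register.

    Returns ``(register, phase_maps)``.  The register has one row per patient
    with any HCC diagnosis flag: ``patient_id, index_month, death_month,
    treatment_type, eligible, exclusion_reason, in_incident_cohort,
    in_death_cohort``.  ``phase_maps`` covers eligible cases only.
    """
    demo = demographics.set_index("patient_id")
    hcc_ids = claims.loc[claims["dx_hcc"].astype(bool), "patient_id"].unique()
    rows = []
    phase_maps: Dict[str, PhaseMap] = {}
    subset = claims[claims["patient_id"].isin(hcc_ids)].copy()
    subset["month"] = month_index_series(subset["month"])
    for pid, timeline in subset.groupby("patient_id", sort=True):
        timeline = timeline.sort_values("month")
        d = demo.loc[pid]
        if pd.isna(d.get("sex")) or pd.isna(d.get("birth_month")):
            raise DataError(f"missing sex or birth_month for patient {pid}")
        death = d.get("death_month")
        death_idx = None if pd.isna(death) or death == "" else month_index(death)
        months = month_index_series(timeline["month"]).to_numpy()
        last_obs = int(months.max())
        first_obs = int(months.min())

        index = find_index_month(timeline, d["birth_month"], lookback, min_age)
        reason = None
        treatment = None
        if index is None:
            reason = "no_eligible_index"
        else:
            end = death_idx if death_idx is not None else last_obs
            treatment = assign_treatment_type(timeline, index, end)
            if treatment is None:
                reason = "no_treatment"
            elif detect_recurrence(timeline, index):
                reason = "recurrence"
        eligible = reason is None
        if eligible:
            phase_maps[pid] = classify_phases(
                index, death_idx, last_obs, first_obs, patient_id=pid
            )
        rows.append(
            {
                "patient_id": pid,
                "index_month": index,
                "death_month": death_idx,
                "first_observed": first_obs,
                "last_observed": last_obs,
                "treatment_type": treatment,
                "eligible": eligible,
                "exclusion_reason": reason,
                "in_incident_cohort": eligible,
                "in_death_cohort": eligible and death_idx is not None,
            }
        )
    register = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "index_month",
            "death_month",
            "first_observed",
            "last_observed",
            "treatment_type",
            "eligible",
            "exclusion_reason",
            "in_incident_cohort",
            "in_death_cohort",
        ],
    )
    return register, phase_maps


def phase_maps_to_frame(phase_maps: Dict[str, PhaseMap]) -> pd.DataFrame:
    """Stack phase maps into a long (patient_id, month, phase) table."""
    if not phase_maps:
        return pd.DataFrame(columns=["patient_id", "month", "phase"])
    return pd.concat(
        [phase_maps[pid].to_frame() for pid in sorted(phase_maps)],
        ignore_index=True,
    )
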