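"""Synthetic longitudinal claims generator.

Generates a seeded panel of patient-months emulating a national claims
extract: every patient is observed from the study start until death or the
study end, with a gamma-distributed monthly baseline expenditure whose mean
scales with age band and comorbidity count, a monthly hazard of incident
hepatocellular carcinoma (HCC), phase-specific incremental costs injected
from the index month onward, and an end-of-life expenditure surge applied to
the last months of *all* decedents (HCC and non-HCC alike) — the mechanism
that drives terminal-phase divergence between matched and within-patient
estimates.

A ground-truth table of the injected quantities accompanies the panel so
every downstream stage can be checked against known values.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .config import AGE_BANDS, PHASES, SimulationConfig
from .months import NEVER, month_index, month_labels
from .phases import classify_phases
from .taxonomy import (
    CCI_COLUMNS,
    CCI_CONDITIONS,
    MODALITIES,
    TREATMENT_MODALITIES,
    TREATMENT_TYPES,
    TX_COLUMNS,
)

CLAIMS_COLUMNS = (
    ["patient_id", "month", "expenditure_yen", "dx_hcc", "dx_other_cancer"]
    + list(CCI_COLUMNS)
    + list(TX_COLUMNS)
)


def _band_bounds(band: str) -> Tuple[int, int]:
    if band.endswith("+"):
        lo = int(band[:-1])
        return lo, lo + 4  # 95+ sampled as 95-99
    lo, hi = band.split("-")
    return int(lo), int(hi)


def _geometric_onsets(rng: np.random.Generator, hazard: float, size) -> np.ndarray:
    """Month offsets (0-based) of first success under a monthly hazard."""
    if hazard <= 0:
        return np.full(size, NEVER, dtype=np.int64)
    return rng.geometric(hazard, size=size).astype(np.int64) - 1


def generate_population(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(claims, demographics, truth)`` tables for one seeded run.

    The claims table has one row per patient-month from the study start to
    death or the study end.  Identical configs (including the seed) produce
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m0 = month_index(config.study_start)
    m1 = month_index(config.study_end)
    n_months = m1 - m0 + 1
    months = np.arange(m0, m1 + 1, dtype=np.int64)
    n = config.n_patients
    ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- demographics -----------------------------------------------------
    female = rng.random(n) < config.sex_prob_female
    bands = list(config.age_dist)
    band_probs = np.array([config.age_dist[b] for b in bands], dtype=float)
    band_probs = band_probs / band_probs.sum()
    band_pick = rng.choice(len(bands), size=n, p=band_probs)
    lo = np.array([_band_bounds(b)[0] for b in bands])[band_pick]
    hi = np.array([_band_bounds(b)[1] for b in bands])[band_pick]
    age0 = lo + rng.integers(0, hi - lo + 1, size=n)  # completed years at entry
    birth = m0 - age0 * 12 - rng.integers(0, 12, size=n)

    # Charlson flags: baseline prevalence plus an optional monthly onset hazard.
    prev = np.array([config.cci_prevalence[c] for c in CCI_CONDITIONS])
    base_flags = rng.random((n, 15)) < prev[None, :]
    onset_offsets = _geometric_onsets(rng, config.cci_onset_hazard, (n, 15))
    cond_onset = np.where(base_flags, np.int64(m0), np.minimum(m0 + 1 + onset_offsets, NEVER))

    # Patient-level baseline mean, normalized so the population mean equals
    # baseline_mean_yen in expectation.
    band_index_all = np.arange(len(AGE_BANDS))
    band_of_patient = np.array([AGE_BANDS.index(bands[k]) for k in band_pick])
    raw_scale = (
        config.age_scale_per_band ** band_of_patient
        * config.cci_scale_per_condition ** base_flags.sum(axis=1)
    )
    expected_scale = float(
        np.sum(
            band_probs
            * config.age_scale_per_band ** np.array([AGE_BANDS.index(b) for b in bands])
        )
        * np.prod(1 - prev + prev * config.cci_scale_per_condition)
    )
    mu = config.baseline_mean_yen * raw_scale / expected_scale

    # --- disease onset and death ------------------------------------------
    hcc_offset = _geometric_onsets(rng, config.hcc_monthly_hazard, n)
    hcc_onset = np.where(hcc_offset >= n_months, NEVER, m0 + np.minimum(hcc_offset, n_months))
    oc_offset = _geometric_onsets(rng, config.other_cancer_monthly_hazard, n)
    oc_onset = np.where(oc_offset >= n_months, NEVER, m0 + np.minimum(oc_offset, n_months))

    death_u = rng.random((n, n_months))
    post = (months[None, :] >= hcc_onset[:, None])
    hazard = np.where(
        post, config.post_hcc_death_hazard, config.background_death_hazard
    )
    dies = death_u < hazard
    any_death = dies.any(axis=1)
    first_death = np.argmax(dies, axis=1)
    death_month = np.where(any_death, m0 + first_death, NEVER)

    is_case = (hcc_onset != NEVER) & (hcc_onset <= np.minimum(death_month, m1))
    hcc_onset = np.where(is_case, hcc_onset, NEVER)

    # --- expenditures -------------------------------------------------------
    gamma = rng.gamma(config.baseline_shape, 1.0, size=(n, n_months))
    baseline = gamma * (mu / config.baseline_shape)[:, None]
    if config.eol_surge_months > 0:
        surge = (
            (death_month[:, None] != NEVER)
            & (months[None, :] > death_month[:, None] - config.eol_surge_months)
            & (months[None, :] <= death_month[:, None])
        )
        baseline = np.where(surge, baseline * config.eol_surge_multiplier, baseline)

    # Treatment types and injected phase increments for cases.
    mix_labels = [t for t in TREATMENT_TYPES if t in config.treatment_mix]
    mix_probs = np.array([config.treatment_mix[t] for t in mix_labels])
    mix_probs = mix_probs / mix_probs.sum()
    case_rows = np.flatnonzero(is_case)
    tt_pick = rng.choice(len(mix_labels), size=len(case_rows), p=mix_probs)

    increments = np.zeros((n, n_months))
    tx_flags = np.zeros((n, n_months, len(MODALITIES)), dtype=bool)
    treatment_of = np.full(n, "", dtype=object)
    # Maintenance-therapy draws (one block, fixed order, for determinism).
    maint_u = rng.random((len(case_rows), n_months))

    mod_pos = {m: j for j, m in enumerate(MODALITIES)}
    for k, i in enumerate(case_rows):
        label = mix_labels[tt_pick[k]]
        treatment_of[i] = label
        onset = int(hcc_onset[i])
        death = int(death_month[i]) if death_month[i] != NEVER else None
        pm = classify_phases(onset, death, m1, first_month=m0)
        modset = sorted(TREATMENT_MODALITIES[label])
        maint = mod_pos[modset[0]]
        for phase in PHASES:
            inc = config.increment(label, phase)
            for m in pm.months(phase):
                if m0 <= m <= m1:
                    increments[i, m - m0] += inc
        # Full modality set administered in the on-treatment initial months.
        for m in range(onset, min(onset + 2, (death if death is not None else m1)) + 1):
            if m > m1 or (death is not None and m > death):
                break
            for mod in modset:
                tx_flags[i, m - m0, mod_pos[mod]] = True
        for phase, p_tx in (("continuing", config.tx_continuing_prob),
                            ("terminal", config.tx_terminal_prob)):
            for m in pm.months(phase):
                if m0 <= m <= m1 and maint_u[k, m - m0] < p_tx:
                    tx_flags[i, m - m0, maint] = True

    expenditure = baseline + increments
    zero_mask = rng.random((n, n_months)) < config.zero_utilization_prob
    expenditure = np.where(zero_mask, 0.0, expenditure)

    # --- assemble long tables ----------------------------------------------
    alive = months[None, :] <= np.minimum(death_month, m1)[:, None]
    n_obs = alive.sum(axis=1)
    row_pid = np.repeat(ids, n_obs)
    flat = alive.ravel()
    row_month = np.tile(months, n)[flat]
    claims = pd.DataFrame(
        {
            "patient_id": row_pid,
            "month": month_labels(row_month),
            "expenditure_yen": np.round(expenditure.ravel()[flat], 2),
            "dx_hcc": ((np.tile(months, n) >= np.repeat(hcc_onset, n_months))[flat]).astype(np.int8),
            "dx_other_cancer": (
                (np.tile(months, n) >= np.repeat(oc_onset, n_months))[flat]
            ).astype(np.int8),
        }
    )
    cond_matrix = months[None, :, None] >= cond_onset[:, None, :]  # n x M x 15
    for j, col in enumerate(CCI_COLUMNS):
        claims[col] = cond_matrix[:, :, j].ravel()[flat].astype(np.int8)
    for j, col in enumerate(TX_COLUMNS):
        claims[col] = tx_flags[:, :, j].ravel()[flat].astype(np.int8)

    demographics = pd.DataFrame(
        {
            "patient_id": ids,
            "sex": np.where(female, "F", "M"),
            "birth_month": month_labels(birth),
            "death_month": [
                month_labels([d])[0] if d != NEVER and d <= m1 else ""
                for d in death_month
            ],
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "is_hcc_case": is_case.astype(np.int8),
            "hcc_index_month": [
                month_labels([o])[0] if o != NEVER else "" for o in hcc_onset
            ],
            "death_month": demographics["death_month"],
            "treatment_type": treatment_of,
            "increment_initial_yen": [
                config.increment(t, "initial") if t else 0.0 for t in treatment_of
            ],
            "increment_continuing_yen": [
                config.increment(t, "continuing") if t else 0.0 for t in treatment_of
            ],
            "increment_terminal_yen": [
                config.increment(t, "terminal") if t else 0.0 for t in treatment_of
            ],
        }
    )
    return claims, demographics, truth
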