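"""Run orchestration: simulate -> classify -> match -> estimate -> compare.

A single structured config (YAML or JSON) drives all stages; every stochastic
stage takes a seed from it, so identical config plus seeds reproduce
byte-identical outputs.  Each stage logs record counts and timing into a run
manifest written next to the result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .adjust import PriceAdjustment, method_comparison, DEFAULT_REVISION_RATES
from .config import SimulationConfig
from .errors import ConfigError, DataError
from .estimators import (
    FEModelSpec,
    TOTAL,
    estimates_frame,
    fixed_effects_estimates,
    index_claims,
    matched_net_estimates,
)
from .matching import condition_onsets, match_death, match_incident
from .months import month_index_series, month_labels
from .phases import build_case_register, phase_maps_to_frame
from .simulate import CLAIMS_COLUMNS, generate_population
from .taxonomy import CCI_COLUMNS, TREATMENT_TYPES, TX_COLUMNS

logger = logging.getLogger("phasecost")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulation: Optional[SimulationConfig] = None
    claims_path: Optional[str] = None
    demographics_path: Optional[str] = None
    matching_seed: int = 0
    pre_window: int = 12
    cov_type: str = "homoskedastic"
    revision_rates: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_REVISION_RATES)
    )
    ppp_yen_per_usd: float = 102.5
    min_cases_per_type: int = 10
    round_report: bool = True

    def adjustment(self) -> PriceAdjustment:
        return PriceAdjustment(
            revision_rates={int(k): float(v) for k, v in self.revision_rates.items()},
            ppp_yen_per_usd=self.ppp_yen_per_usd,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_claims(claims) -> List[str]:
    """Schema and consistency checks for a claims table (path or DataFrame).

    Returns a list of error strings; empty means the table is valid.
    """
    if not isinstance(claims, pd.DataFrame):
        claims = pd.read_csv(claims, dtype={"month": str})
    errors: List[str] = []
    missing = [c for c in CLAIMS_COLUMNS if c not in claims.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return errors
    bad_month = ~claims["month"].astype(str).str.match(r"^\d{4}-(0[1-9]|1[0-2])$")
    for row in claims.index[bad_month][:10]:
        errors.append(f"row {row}: month {claims.at[row, 'month']!r} is not YYYY-MM")
    neg = claims["expenditure_yen"] < 0
    for row in claims.index[neg][:10]:
        errors.append(
            f"row {row}: negative expenditure {claims.at[row, 'expenditure_yen']}"
        )
    for col in ("dx_hcc", "dx_other_cancer", *CCI_COLUMNS, *TX_COLUMNS):
        vals = set(pd.unique(claims[col]))
        if not vals <= {0, 1}:
            errors.append(f"column {col}: non-binary values {sorted(vals - {0, 1})[:5]}")
    dup = claims.duplicated(subset=["patient_id", "month"])
    for row in claims.index[dup][:10]:
        errors.append(
            f"row {row}: duplicated patient-month "
            f"({claims.at[row, 'patient_id']}, {claims.at[row, 'month']})"
        )
    if not bad_month.any():
        m = month_index_series(claims["month"])
        diffs = m.groupby(claims["patient_id"].to_numpy()).diff()
        if (diffs.dropna() <= 0).any():
            errors.append("months are not strictly increasing within a patient")
    return errors


def _fmt_months(values) -> List[str]:
    return [month_labels([v])[0] if pd.notna(v) and v is not None else "" for v in values]


def _parse_month(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    from .months import month_index

    return month_index(value)


# ---------------------------------------------------------------------------
# Stage I/O: each stage reads its inputs from and writes its outputs into one
# working directory, so the CLI can run stages separately or chained.
# ---------------------------------------------------------------------------

def load_claims(directory) -> Tuple[pd.DataFrame, pd.DataFrame]:
    d = Path(directory)
    claims = pd.read_csv(d / "claims.csv", dtype={"month": str})
    demographics = pd.read_csv(
        d / "demographics.csv",
        dtype={"birth_month": str, "death_month": str},
        keep_default_na=False,
    )
    return claims, demographics


def write_register(register: pd.DataFrame, directory) -> None:
    out = register.copy()
    for col in ("index_month", "death_month", "first_observed", "last_observed"):
        out[col] = _fmt_months(out[col])
    out.to_csv(Path(directory) / "case_register.csv", index=False)


def read_register(directory) -> pd.DataFrame:
    reg = pd.read_csv(Path(directory) / "case_register.csv", keep_default_na=False)
    for col in ("index_month", "death_month", "first_observed", "last_observed"):
        reg[col] = [_parse_month(v) for v in reg[col]]
    for col in ("eligible", "in_incident_cohort", "in_death_cohort"):
        reg[col] = reg[col].astype(str).str.lower() == "true"
    reg["exclusion_reason"] = reg["exclusion_reason"].replace("", None)
    return reg


def read_phase_maps(directory) -> Dict[str, "PhaseMap"]:
    from .phases import PhaseMap

    long = pd.read_csv(Path(directory) / "phase_map.csv", dtype={"month": str})
    long["_m"] = month_index_series(long["month"])
    out: Dict[str, PhaseMap] = {}
    for pid, rows in long.groupby("patient_id"):
        out[pid] = PhaseMap(
            patient_id=pid,
            assignments=dict(zip(rows["_m"].tolist(), rows["phase"])),
        )
    return out


def stage_input(config: RunConfig, out: Path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a panel (writing it) or load the configured claims CSVs."""
    if config.simulation is not None:
        claims, demographics, truth = generate_population(config.simulation)
        claims.to_csv(out / "claims.csv", index=False)
        demographics.to_csv(out / "demographics.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    elif config.claims_path and config.demographics_path:
        claims = pd.read_csv(config.claims_path, dtype={"month": str})
        demographics = pd.read_csv(
            config.demographics_path,
            dtype={"birth_month": str, "death_month": str},
            keep_default_na=False,
        )
    else:
        raise ConfigError(
            "either simulation or claims_path+demographics_path must be set"
        )
    problems = validate_claims(claims)
    if problems:
        raise DataError("claims validation failed: " + "; ".join(problems[:5]))
    return claims, demographics


def stage_classify(claims, demographics, out: Path):
    """Screen cases, assign phases; write case_register.csv and phase_map.csv."""
    register, phase_maps = build_case_register(claims, demographics)
    write_register(register, out)
    phase_maps_to_frame(phase_maps).to_csv(out / "phase_map.csv", index=False)
    return register, phase_maps


def stage_match(config: RunConfig, register, claims, demographics, out: Path):
    """Match both cohorts; write pairs.csv and unmatched.csv."""
    pairs_i, unmatched_i = match_incident(
        register, claims, demographics, config.matching_seed
    )
    pairs_d, unmatched_d = match_death(
        register, claims, demographics, config.matching_seed
    )
    pairs = pd.concat([pairs_i, pairs_d], ignore_index=True)
    unmatched = pd.concat(
        [unmatched_i.assign(cohort="incident"), unmatched_d.assign(cohort="death")],
        ignore_index=True,
    )
    pairs.to_csv(out / "pairs.csv", index=False)
    unmatched.to_csv(out / "unmatched.csv", index=False)
    return pairs_i, unmatched_i, pairs_d, unmatched_d


def stage_estimate(config: RunConfig, register, phase_maps, claims, demographics,
                   pairs_i, pairs_d, out: Path) -> pd.DataFrame:
    """Both estimators for Total and every sufficiently large treatment type."""
    adjuster = config.adjustment()
    cindex = index_claims(claims, adjuster)
    onsets = condition_onsets(claims)
    estimates = []
    type_counts = register[register["eligible"]]["treatment_type"].value_counts()
    strata = [TOTAL] + [
        t for t in TREATMENT_TYPES if type_counts.get(t, 0) >= config.min_cases_per_type
    ]
    matched_ids_i = pairs_i["case_id"].tolist()
    matched_ids_d = pairs_d["case_id"].tolist()
    for tt in strata:
        for phase, cohort_pairs in (
            ("initial", pairs_i),
            ("continuing", pairs_i),
            ("terminal", pairs_d),
        ):
            try:
                estimates.append(
                    matched_net_estimates(
                        cohort_pairs, phase_maps, cindex, register, tt, phase
                    )
                )
            except Exception as exc:  # stratum too sparse
                logger.warning("matched %s/%s skipped: %s", tt, phase, exc)
        for cohort, ids in (("incident", matched_ids_i), ("death", matched_ids_d)):
            try:
                estimates.extend(
                    fixed_effects_estimates(
                        register, phase_maps, cindex, demographics, onsets,
                        FEModelSpec(
                            cohort=cohort,
                            pre_window=config.pre_window,
                            cov_type=config.cov_type,
                        ),
                        tt, case_ids=ids,
                    )
                )
            except Exception as exc:
                logger.warning("fixed-effects %s/%s skipped: %s", tt, cohort, exc)
    est_df = estimates_frame(estimates)
    if config.round_report:
        for col in ("reference_usd_pppm", "net_usd_pppm", "ci_low", "ci_high"):
            est_df[col] = est_df[col].round(2)
    est_df.to_csv(out / "estimates.csv", index=False)
    return est_df


def stage_compare(config: RunConfig, est_df: pd.DataFrame, out: Path) -> pd.DataFrame:
    """Method-comparison table (proportional and absolute differences)."""
    comparison = method_comparison(est_df)
    if config.round_report:
        comparison["proportional_difference_pct"] = (
            100 * comparison["proportional_difference"]
        ).round(1)
        comparison["absolute_difference"] = comparison["absolute_difference"].round(0)
    comparison.to_csv(out / "comparison.csv", index=False)
    return comparison


def run_pipeline(config: RunConfig, out_dir) -> Dict[str, object]:
    """Execute all stages and write result tables plus a manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "config_hash": config.config_hash(),
        "matching_seed": config.matching_seed,
        "stages": {},
    }
    if config.simulation is not None:
        manifest["simulation_seed"] = config.simulation.seed

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **counts,
            }
            logger.info("stage %s done: %s", name, counts)

        return done

    end = stage("input")
    claims, demographics = stage_input(config, out)
    end(rows=len(claims), patients=demographics["patient_id"].nunique())

    end = stage("classify")
    register, phase_maps = stage_classify(claims, demographics, out)
    n_eligible = int(register["eligible"].sum())
    end(
        screened=len(register),
        eligible=n_eligible,
        recurrence_excluded=int((register["exclusion_reason"] == "recurrence").sum()),
    )

    end = stage("match")
    pairs_i, unmatched_i, pairs_d, unmatched_d = stage_match(
        config, register, claims, demographics, out
    )
    end(
        incident_pairs=len(pairs_i),
        incident_unmatched=len(unmatched_i),
        death_pairs=len(pairs_d),
        death_unmatched=len(unmatched_d),
    )

    end = stage("estimate")
    est_df = stage_estimate(
        config, register, phase_maps, claims, demographics, pairs_i, pairs_d, out
    )
    end(estimates=len(est_df))

    end = stage("compare")
    comparison = stage_compare(config, est_df, out)
    end(rows=len(comparison))

    manifest["counts"] = {
        "eligible": n_eligible,
        "incident_matched_plus_unmatched": len(pairs_i) + len(unmatched_i),
        "death_matched_plus_unmatched": len(pairs_d) + len(unmatched_d),
        "incident_eligible": int(register["in_incident_cohort"].sum()),
        "death_eligible": int(register["in_death_cohort"].sum()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
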