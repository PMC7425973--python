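"""Simulation configuration for the synthetic claims generator.

The generator emulates the structure of a national claims extract:
per-provider-aggregated monthly expenditures, hepatocellular-carcinoma (HCC)
and other-cancer diagnosis flags, 15 Charlson condition flags, 7 treatment-
modality flags, and a death month, over an April-2010-to-March-2018-style
study window.  Incremental phase-specific costs and a common end-of-life
expenditure surge are injected on top of a gamma-distributed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple, Union

from .errors import ConfigError
from .months import month_index
from .taxonomy import CCI_CONDITIONS, TREATMENT_TYPES

PHASES = ("initial", "continuing", "terminal")

#: 5-year age bands used for matching; 95+ is open-ended.
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(20, 95, 5)) + ("95+",)

#: Default population prevalence per Charlson condition (liver disease enriched,
#: as expected of an HCC-era claims extract).
DEFAULT_CCI_PREVALENCE: Dict[str, float] = {
    "myocardial_infarction": 0.01,
    "congestive_heart_failure": 0.05,
    "peripheral_vascular_disease": 0.02,
    "cerebrovascular_disease": 0.04,
    "dementia": 0.02,
    "copd": 0.04,
    "rheumatic_disease": 0.01,
    "peptic_ulcer": 0.10,
    "mild_liver_disease": 0.25,
    "diabetes": 0.12,
    "diabetes_complications": 0.03,
    "hemiplegia": 0.003,
    "renal_disease": 0.02,
    "moderate_severe_liver_disease": 0.04,
    "aids": 0.0003,
}

#: Default age distribution (HCC presents mostly in the 60s–80s).
DEFAULT_AGE_DIST: Dict[str, float] = {
    "50-54": 0.05,
    "55-59": 0.08,
    "60-64": 0.12,
    "65-69": 0.17,
    "70-74": 0.20,
    "75-79": 0.18,
    "80-84": 0.12,
    "85-89": 0.08,
}

#: Default treatment-type mix among incident HCC cases.
DEFAULT_TREATMENT_MIX: Dict[str, float] = {
    "Surgical resection only": 0.238,
    "Surgical resection + LRT": 0.003,
    "Surgical resection + TACE/TAE": 0.014,
    "Surgical resection + others": 0.034,
    "LRT only": 0.137,
    "LRT + TACE/TAE": 0.048,
    "LRT + chemotherapy": 0.016,
    "LRT + others": 0.010,
    "TACE only": 0.152,
    "TACE + chemotherapy": 0.017,
    "TACE + chemotherapy + sorafenib": 0.006,
    "TAE only": 0.005,
    "TAE + chemotherapy": 0.002,
    "Sorafenib only": 0.013,
    "Sorafenib + chemotherapy": 0.018,
    "Others": 0.287,
}

#: Default injected incremental cost per phase, yen per month, applied to all
#: treatment types.  Magnitudes mirror national-scale per-phase net estimates
#: (roughly $3.7k / $0.3k / $3k a month at 102.5 yen per dollar).
DEFAULT_PHASE_INCREMENT_YEN: Dict[str, float] = {
    "initial": 380_000.0,
    "continuing": 30_000.0,
    "terminal": 310_000.0,
}


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= float(value) <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic claims panel.

    ``phase_increment_yen`` may be either a ``{phase: yen}`` map (broadcast to
    every treatment type) or a ``{(treatment_type, phase): yen}`` map.
    """

    n_patients: int = 2000
    study_start: str = "2010-04"
    study_end: str = "2018-03"
    seed: int = 0
    baseline_mean_yen: float = 65_000.0
    baseline_shape: float = 2.0
    age_dist: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    sex_prob_female: float = 0.35
    cci_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CCI_PREVALENCE)
    )
    hcc_monthly_hazard: float = 0.0015
    treatment_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_MIX)
    )
    phase_increment_yen: Mapping[Union[str, Tuple[str, str]], float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_INCREMENT_YEN)
    )
    post_hcc_death_hazard: float = 0.03
    background_death_hazard: float = 0.003
    eol_surge_months: int = 6
    eol_surge_multiplier: float = 3.0
    zero_utilization_prob: float = 0.10
    # Baseline heterogeneity: a patient's mean expenditure scales multiplicatively
    # with age band and baseline Charlson flag count so matching is informative.
    age_scale_per_band: float = 1.05
    cci_scale_per_condition: float = 1.08
    # Optional monthly onset hazard for Charlson conditions (time-dependent CCI).
    cci_onset_hazard: float = 0.002
    other_cancer_monthly_hazard: float = 0.0005
    # Probability an anticancer modality is re-administered in a continuing /
    # terminal month (keeps treated survivors from tripping the recurrence rule).
    tx_continuing_prob: float = 0.35
    tx_terminal_prob: float = 0.15

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        start, end = month_index(self.study_start), month_index(self.study_end)
        if start >= end:
            raise ConfigError("study_start must precede study_end")
        if self.baseline_mean_yen <= 0:
            raise ConfigError("baseline_mean_yen must be positive")
        if self.baseline_shape <= 0:
            raise ConfigError("baseline_shape must be positive")
        _check_prob("sex_prob_female", self.sex_prob_female)
        _check_prob("hcc_monthly_hazard", self.hcc_monthly_hazard)
        _check_prob("post_hcc_death_hazard", self.post_hcc_death_hazard)
        _check_prob("background_death_hazard", self.background_death_hazard)
        _check_prob("zero_utilization_prob", self.zero_utilization_prob)
        _check_prob("cci_onset_hazard", self.cci_onset_hazard)
        _check_prob("other_cancer_monthly_hazard", self.other_cancer_monthly_hazard)
        _check_prob("tx_continuing_prob", self.tx_continuing_prob)
        _check_prob("tx_terminal_prob", self.tx_terminal_prob)
        if self.eol_surge_months < 0:
            raise ConfigError("eol_surge_months must be >= 0")
        if self.eol_surge_multiplier <= 0:
            raise ConfigError("eol_surge_multiplier must be positive")
        for band in self.age_dist:
            if band not in AGE_BANDS:
                raise ConfigError(f"age_dist contains unknown band {band!r}")
        if abs(sum(self.age_dist.values()) - 1.0) > 1e-9:
            raise ConfigError("age_dist probabilities must sum to 1")
        missing = set(CCI_CONDITIONS) - set(self.cci_prevalence)
        if missing:
            raise ConfigError(f"cci_prevalence missing conditions: {sorted(missing)}")
        for cond in CCI_CONDITIONS:
            _check_prob(f"cci_prevalence[{cond}]", self.cci_prevalence[cond])
        for label in self.treatment_mix:
            if label not in TREATMENT_TYPES:
                raise ConfigError(f"treatment_mix contains unknown type {label!r}")
        if abs(sum(self.treatment_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("treatment_mix probabilities must sum to 1")
        for key, value in self.phase_increment_yen.items():
            phase = key[1] if isinstance(key, tuple) else key
            if phase not in PHASES:
                raise ConfigError(f"phase_increment_yen has unknown phase {key!r}")
            if value < 0:
                raise ConfigError(f"phase_increment_yen[{key!r}] must be >= 0")
        return self

    def increment(self, treatment_type: str, phase: str) -> float:
        """Injected incremental cost (yen/month) for a treatment type and phase."""
        inc = self.phase_increment_yen
        if (treatment_type, phase) in inc:
            return float(inc[(treatment_type, phase)])
        return float(inc.get(phase, 0.0))

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


def age_band_of(age_years: int) -> str:
    """5-year age band label for an age in completed years (adults only)."""
    age = int(age_years)
    if age < 20:
        raise ConfigError(f"age bands are defined for adults (>=20), got {age}")
    if age >= 95:
        return "95+"
    lo = age - (age - 20) % 5
    return f"{lo}-{lo + 4}"
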