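"""Domain vocabularies: Charlson conditions, treatment modalities, treatment types.

The comorbidity set is the Charlson comorbidity index restricted to the 15
non-malignancy conditions (tumours and metastatic solid tumours are excluded
because every case has a malignancy by definition).  Treatment types are the
16 categories used to stratify hepatocellular-carcinoma expenditure
estimates: single modalities, the common named combinations, and a residual
"Others" bucket.
"""

from __future__ import annotations

from typing import FrozenSet

#: The 15 Charlson conditions (fixed order; matching keys and CSV columns use it).
CCI_CONDITIONS = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "copd",
    "rheumatic_disease",
    "peptic_ulcer",
    "mild_liver_disease",
    "diabetes",
    "diabetes_complications",
    "hemiplegia",
    "renal_disease",
    "moderate_severe_liver_disease",
    "aids",
)

CCI_COLUMNS = tuple(f"cci_{c}" for c in CCI_CONDITIONS)

#: Original Charlson weights for the 15 conditions above (same order).
_WEIGHT_BY_CONDITION = {
    "mild_liver_disease": 1,
    "diabetes": 1,
    "diabetes_complications": 2,
    "hemiplegia": 2,
    "renal_disease": 2,
    "moderate_severe_liver_disease": 3,
    "aids": 6,
}
CHARLSON_WEIGHTS = tuple(_WEIGHT_BY_CONDITION.get(c, 1) for c in CCI_CONDITIONS)

#: Anticancer treatment modalities tracked as monthly procedure flags.
MODALITIES = ("resection", "lrt", "tace", "tae", "sorafenib", "chemo", "radiotherapy")
TX_COLUMNS = tuple(f"tx_{m}" for m in MODALITIES)

#: The 16 treatment-type categories.
TREATMENT_TYPES = (
    "Surgical resection only",
    "Surgical resection + LRT",
    "Surgical resection + TACE/TAE",
    "Surgical resection + others",
    "LRT only",
    "LRT + TACE/TAE",
    "LRT + chemotherapy",
    "LRT + others",
    "TACE only",
    "TACE + chemotherapy",
    "TACE + chemotherapy + sorafenib",
    "TAE only",
    "TAE + chemotherapy",
    "Sorafenib only",
    "Sorafenib + chemotherapy",
    "Others",
)

#: Representative modality set per treatment type, used by the claims generator.
TREATMENT_MODALITIES = {
    "Surgical resection only": frozenset({"resection"}),
    "Surgical resection + LRT": frozenset({"resection", "lrt"}),
    "Surgical resection + TACE/TAE": frozenset({"resection", "tace"}),
    "Surgical resection + others": frozenset({"resection", "chemo"}),
    "LRT only": frozenset({"lrt"}),
    "LRT + TACE/TAE": frozenset({"lrt", "tace"}),
    "LRT + chemotherapy": frozenset({"lrt", "chemo"}),
    "LRT + others": frozenset({"lrt", "radiotherapy"}),
    "TACE only": frozenset({"tace"}),
    "TACE + chemotherapy": frozenset({"tace", "chemo"}),
    "TACE + chemotherapy + sorafenib": frozenset({"tace", "chemo", "sorafenib"}),
    "TAE only": frozenset({"tae"}),
    "TAE + chemotherapy": frozenset({"tae", "chemo"}),
    "Sorafenib only": frozenset({"sorafenib"}),
    "Sorafenib + chemotherapy": frozenset({"sorafenib", "chemo"}),
    "Others": frozenset({"chemo"}),
}


def treatment_type_for(modalities: FrozenSet[str]) -> str:
    """Map an observed set of treatment modalities to its treatment-type label.

    The mapping is total over all modality subsets and keyed on the most
    specific named category: resection-containing sets map to the four
    resection rows, then LRT-containing sets, then the exact TACE / TAE /
    sorafenib combinations; anything else (including empty handled upstream)
    falls through to ``"Others"``.  ``TACE/TAE`` rows absorb TACE, TAE or both.
    """
    mods = frozenset(modalities)
    unknown = mods - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown treatment modalities: {sorted(unknown)}")
    embol = mods & {"tace", "tae"}
    if "resection" in mods:
        rest = mods - {"resection"}
        if not rest:
            return "Surgical resection only"
        if rest == {"lrt"}:
            return "Surgical resection + LRT"
        if rest and rest <= {"tace", "tae"}:
            return "Surgical resection + TACE/TAE"
        return "Surgical resection + others"
    if "lrt" in mods:
        rest = mods - {"lrt"}
        if not rest:
            return "LRT only"
        if rest and rest <= {"tace", "tae"}:
            return "LRT + TACE/TAE"
        if rest == {"chemo"}:
            return "LRT + chemotherapy"
        return "LRT + others"
    if mods == {"tace"}:
        return "TACE only"
    if mods == {"tace", "chemo"}:
        return "TACE + chemotherapy"
    if mods == {"tace", "chemo", "sorafenib"}:
        return "TACE + chemotherapy + sorafenib"
    if mods == {"tae"}:
        return "TAE only"
    if mods == {"tae", "chemo"}:
        return "TAE + chemotherapy"
    if mods == {"sorafenib"}:
        return "Sorafenib only"
    if mods == {"sorafenib", "chemo"}:
        return "Sorafenib + chemotherapy"
    return "Others"


def cci_score(flags) -> int:
    """Weighted Charlson score from the 15 condition flags (fixed order)."""
    return int(sum(w * int(bool(f)) for w, f in zip(CHARLSON_WEIGHTS, flags)))
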