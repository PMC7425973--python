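import numpy as np
import pandas as pd
import pytest

from phasecost.months import month_index, month_labels
from phasecost.taxonomy import CCI_COLUMNS, TX_COLUMNS


def make_timeline(start, n_months, dx_hcc=(), dx_other_cancer=(), tx=None,
                  expenditure=None):
    """Small claims timeline for one patient.

    ``dx_hcc`` / ``dx_other_cancer`` are iterables of YYYY-MM months flagged;
    ``tx`` maps modality name -> iterable of flagged months; ``expenditure``
    maps YYYY-MM -> yen (default 1000 everywhere).
    """
    m0 = month_index(start)
    months = np.arange(m0, m0 + n_months)
    df = pd.DataFrame({"patient_id": "P1", "month": month_labels(months)})
    hcc = {month_index(m) for m in dx_hcc}
    oc = {month_index(m) for m in dx_other_cancer}
    df["expenditure_yen"] = [
        (expenditure or {}).get(lbl, 1000.0) for lbl in df["month"]
    ]
    df["dx_hcc"] = [int(m in hcc) for m in months]
    df["dx_other_cancer"] = [int(m in oc) for m in months]
    for col in CCI_COLUMNS:
        df[col] = 0
    tx = tx or {}
    flagged = {mod: {month_index(m) for m in ms} for mod, ms in tx.items()}
    for col, mod in zip(TX_COLUMNS, ("resection", "lrt", "tace", "tae",
                                     "sorafenib", "chemo", "radiotherapy")):
        df[col] = [int(m in flagged.get(mod, ())) for m in months]
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
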