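"""Calendar-month arithmetic.

All tables in this package use first-of-month semantics with months written
as ``YYYY-MM``.  Internally a month is an integer index (months since year
0), which makes phase windows, lookbacks and anchor offsets plain integer
arithmetic.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")

#: Sentinel for "never happens" (condition never onsets, patient never dies).
NEVER = 10**9


def month_index(month) -> int:
    """Convert ``YYYY-MM`` (or an already-converted integer) to a month index."""
    if isinstance(month, (int, np.integer)):
        return int(month)
    if isinstance(month, pd.Period):
        return month.year * 12 + month.month - 1
    m = _MONTH_RE.match(str(month))
    if m is None:
        raise ValueError(f"not a YYYY-MM month: {month!r}")
    year, mon = int(m.group(1)), int(m.group(2))
    if not 1 <= mon <= 12:
        raise ValueError(f"month out of range in {month!r}")
    return year * 12 + (mon - 1)


def month_label(index: int) -> str:
    """Convert a month index back to ``YYYY-MM``."""
    index = int(index)
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


def month_index_series(months: pd.Series) -> pd.Series:
    """Vectorized :func:`month_index` for a Series of ``YYYY-MM`` strings."""
    if pd.api.types.is_integer_dtype(months):
        return months.astype(np.int64)
    if len(months) == 0:
        return pd.Series([], dtype=np.int64, index=months.index)
    parts = months.astype(str).str.split("-", expand=True)
    return parts[0].astype(np.int64) * 12 + (parts[1].astype(np.int64) - 1)


def month_labels(indices) -> np.ndarray:
    """Vectorized :func:`month_label`."""
    idx = np.asarray(indices, dtype=np.int64)
    years = idx // 12
    mons = idx % 12 + 1
    return np.char.add(
        np.char.add(np.char.zfill(years.astype(str), 4), "-"),
        np.char.zfill(mons.astype(str), 2),
    )


def age_in_years(month: int, birth_month: int) -> int:
    """Age in completed years at the first of ``month``."""
    return (int(month) - int(birth_month)) // 12
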