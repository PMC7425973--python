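"""Price-revision adjustment, currency conversion, and method comparison.

Japanese reimbursement prices are revised every two fiscal years (a fiscal
year runs April through March), so expenditures from different service months
are first deflated to a common 2018 price level with the published revision
rates, aggregated, and only then converted to US dollars once with the 2017
purchasing-power-parity rate of 102.5 yen per dollar.

The two method-comparison statistics are::

    proportional difference = 1 - matched / fixed-effects
    absolute difference     = fixed-effects - matched
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, EstimationError
from .months import month_index

#: Revision rates relative to 2018 prices, keyed by fiscal year (April-March).
DEFAULT_REVISION_RATES: Dict[int, float] = {
    2010: 1.019,
    2011: 1.019,
    2012: 1.004,
    2013: 1.004,
    2014: 1.1001,
    2015: 1.1001,
    2016: 0.9916,
    2017: 0.9916,
}

PPP_YEN_PER_USD = 102.5


def fiscal_year(month) -> int:
    """Japanese fiscal year (April-March) containing a calendar month."""
    idx = month_index(month)
    year, mon = idx // 12, idx % 12 + 1
    return year if mon >= 4 else year - 1


@dataclass(frozen=True)
class PriceAdjustment:
    """Revision-rate multipliers per fiscal year plus the PPP conversion rate."""

    revision_rates: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_REVISION_RATES)
    )
    ppp_yen_per_usd: float = PPP_YEN_PER_USD

    def __post_init__(self):
        for fy, rate in self.revision_rates.items():
            if rate <= 0:
                raise ConfigError(f"revision_rates[{fy}] must be positive, got {rate}")
        if self.ppp_yen_per_usd <= 0:
            raise ConfigError("ppp_yen_per_usd must be positive")

    def multiplier(self, month) -> float:
        fy = fiscal_year(month)
        try:
            return float(self.revision_rates[fy])
        except KeyError:
            raise ConfigError(
                f"no revision rate configured for fiscal year {fy} "
                f"(service month {month!r})"
            ) from None

    def multipliers(self, months) -> np.ndarray:
        """Vectorized multiplier lookup over an array of month indices."""
        months = np.asarray(months)
        fys = months // 12 - (months % 12 + 1 < 4)
        out = np.empty(len(months), dtype=float)
        for fy in np.unique(fys):
            if int(fy) not in self.revision_rates:
                raise ConfigError(f"no revision rate configured for fiscal year {fy}")
            out[fys == fy] = self.revision_rates[int(fy)]
        return out

    def adjust(self, amount_yen: float, month) -> float:
        """Deflate an expenditure from its service month to base-year prices."""
        return float(amount_yen) * self.multiplier(month)

    def to_usd(self, amount_yen: float) -> float:
        return float(amount_yen) / self.ppp_yen_per_usd


def adjust_expenditure(amount_yen: float, month, adjustment: PriceAdjustment) -> float:
    """Apply the service-month revision rate to a yen amount."""
    return adjustment.adjust(amount_yen, month)


def yen_to_usd(amount_yen: float, adjustment: PriceAdjustment = None) -> float:
    """Convert yen to US dollars at the purchasing-power-parity rate."""
    rate = PPP_YEN_PER_USD if adjustment is None else adjustment.ppp_yen_per_usd
    return float(amount_yen) / rate


def proportional_difference(matched_estimate: float, fe_estimate: float) -> float:
    """``1 - matched / fixed-effects`` (dimensionless; reported as a percentage)."""
    if fe_estimate == 0:
        raise EstimationError(
            "proportional difference is undefined: fixed-effects estimate is 0"
        )
    return 1.0 - matched_estimate / fe_estimate


def absolute_difference(matched_estimate: float, fe_estimate: float) -> float:
    """``fixed-effects - matched`` in the estimates' own units (USD per month)."""
    return fe_estimate - matched_estimate


def method_comparison(estimates: pd.DataFrame) -> pd.DataFrame:
    """Build the method-comparison table from a tidy estimates table.

    ``estimates`` needs columns ``method`` (``matched`` / ``fixed_effects``),
    ``treatment_type``, ``phase`` and ``net_usd_pppm``.  Returns one row per
    (treatment_type, phase) present under both methods, with
    ``proportional_difference`` (fraction; NaN where the fixed-effects
    estimate is exactly 0) and ``absolute_difference`` (USD per month).
    """
    wide = estimates.pivot_table(
        index=["treatment_type", "phase"],
        columns="method",
        values="net_usd_pppm",
        aggfunc="first",
    )
    if not {"matched", "fixed_effects"} <= set(wide.columns):
        raise EstimationError("need both matched and fixed_effects estimates")
    wide = wide.dropna(subset=["matched", "fixed_effects"])
    out = wide.reset_index()
    fe = out["fixed_effects"].to_numpy(float)
    matched = out["matched"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(fe != 0, 1.0 - matched / fe, np.nan)
    out["proportional_difference"] = prop
    out["absolute_difference"] = fe - matched
    return out[
        [
            "treatment_type",
            "phase",
            "matched",
            "fixed_effects",
            "proportional_difference",
            "absolute_difference",
        ]
    ]
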