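"""Net expenditure estimators: matched paired comparison and within-patient OLS.

Both methods target the disease-associated expenditure per patient per month
(PPPM) by treatment type and phase of care, on price-adjusted USD:

* the **matched comparison** takes, per matched pair, the difference between
  the case's PPPM over its phase months and the control's PPPM over the same
  months (shifted by the pair's anchor offset), and summarizes the paired
  differences with a t confidence interval;
* the **fixed-effects (within) analysis** regresses monthly expenditure on
  phase indicators plus time-dependent age and Charlson score after removing
  patient-specific means, so each patient acts as their own control; the phase
  coefficients are the net estimates and the pre-disease months supply the
  reference level.

Months without any healthcare utilization count as zero expenditure in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .adjust import PriceAdjustment
from .errors import DataError, EstimationError, SingularDesignError
from .months import NEVER, month_index, month_index_series
from .phases import PhaseMap
from .taxonomy import CCI_COLUMNS, CHARLSON_WEIGHTS

DEFAULT_PRE_WINDOW = 12
TOTAL = "Total"


@dataclass
class NetEstimate:
    """One treatment x phase x method net-expenditure estimate (USD PPPM)."""

    method: str  # 'matched' | 'fixed_effects'
    cohort: str  # 'incident' | 'death'
    treatment_type: str
    phase: str
    net_usd_pppm: float
    ci_low: float
    ci_high: float
    n: int
    reference_usd_pppm: float = float("nan")
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "cohort": self.cohort,
            "treatment_type": self.treatment_type,
            "phase": self.phase,
            "n": self.n,
            "reference_usd_pppm": self.reference_usd_pppm,
            "net_usd_pppm": self.net_usd_pppm,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "notes": self.notes,
        }


def estimates_frame(estimates: Iterable[NetEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in estimates])


# ---------------------------------------------------------------------------
# PPPM
# ---------------------------------------------------------------------------

def pppm(expenditure_by_month: Mapping[int, float], months: Sequence[int],
         adjuster: Optional[PriceAdjustment] = None) -> float:
    """Mean (price-adjusted) expenditure over a month set, zeros retained.

    Months absent from ``expenditure_by_month`` count as zero-utilization
    months.  Returns adjusted yen per month (convert to USD separately).
    """
    months = list(months)
    if not months:
        raise EstimationError("PPPM is undefined over an empty month set")
    total = 0.0
    for m in months:
        amount = float(expenditure_by_month.get(int(m), 0.0))
        total += amount if adjuster is None else adjuster.adjust(amount, m)
    return total / len(months)


# ---------------------------------------------------------------------------
# Paired matched comparison
# ---------------------------------------------------------------------------

class PairedDifference(BaseEstimator):
    """Mean of paired differences with a Student-t confidence interval.

    Attributes (after ``fit``): ``mean_``, ``sd_``, ``n_``, ``ci_low_``,
    ``ci_high_``, ``degenerate_`` (True when n < 2 and the CI is undefined).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, case_values, control_values=None) -> "PairedDifference":
        case_values = np.asarray(case_values, dtype=float)
        if control_values is not None:
            control_values = np.asarray(control_values, dtype=float)
            if case_values.shape != control_values.shape:
                raise DataError("case and control value arrays differ in length")
            d = case_values - control_values
        else:
            d = case_values
        if d.size == 0:
            raise EstimationError("no pairs to compare")
        self.diffs_ = d
        self.n_ = int(d.size)
        self.mean_ = float(d.mean())
        if self.n_ >= 2:
            self.sd_ = float(d.std(ddof=1))
            tcrit = float(stats.t.ppf(1 - self.alpha / 2, self.n_ - 1))
            half = tcrit * self.sd_ / np.sqrt(self.n_)
            self.ci_low_ = self.mean_ - half
            self.ci_high_ = self.mean_ + half
            self.degenerate_ = False
        else:
            self.sd_ = float("nan")
            self.ci_low_ = float("nan")
            self.ci_high_ = float("nan")
            self.degenerate_ = True
        return self


# ---------------------------------------------------------------------------
# Within (fixed-effects) OLS
# ---------------------------------------------------------------------------

class WithinRegressor(BaseEstimator, RegressorMixin):
    """Fixed-effects panel OLS via within-patient demeaning.

    Equivalent to least squares with one indicator per patient: outcome and
    regressors are demeaned within each group, OLS is run on the demeaned
    data, and the residual degrees of freedom are corrected to
    ``n_obs - n_groups - n_regressors``.

    Parameters
    ----------
    cov_type : {'homoskedastic', 'cluster'}
        Conventional OLS standard errors on the demeaned data (default), or
        cluster-robust by group.
    alpha : float
        Confidence level for ``conf_int`` is ``1 - alpha``.

    Attributes
    ----------
    coef_, bse_, cov_params_ : ndarray
    df_resid_, n_groups_, n_obs_ : int
    group_effects_ : dict group -> fitted intercept
    """

    def __init__(self, cov_type: str = "homoskedastic", alpha: float = 0.05):
        self.cov_type = cov_type
        self.alpha = alpha

    def fit(self, X, y, groups) -> "WithinRegressor":
        if self.cov_type not in ("homoskedastic", "cluster"):
            raise ValueError(f"unknown cov_type {self.cov_type!r}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.feature_names_in_ = np.array(
                [f"x{j}" for j in range(X.shape[1])], dtype=object
            )
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        n, k = X.shape
        if y.shape != (n,) or groups.shape != (n,):
            raise DataError("X, y and groups must have matching first dimension")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise DataError("X and y must be finite")

        codes, uniques = pd.factorize(groups)
        g = len(uniques)
        counts = np.bincount(codes)
        ym = np.bincount(codes, weights=y) / counts
        Xd = np.empty_like(X)
        for j in range(k):
            Xd[:, j] = X[:, j] - (np.bincount(codes, weights=X[:, j]) / counts)[codes]
        yd = y - ym[codes]

        df = n - g - k
        if df <= 0:
            raise EstimationError(
                f"not enough observations: n={n}, groups={g}, regressors={k}"
            )
        norms = np.sqrt((Xd**2).sum(axis=0))
        scale = np.sqrt((X**2).sum(axis=0))
        scale[scale == 0] = 1.0
        dead = norms <= 1e-10 * np.maximum(scale, 1.0)
        if dead.any():
            raise SingularDesignError(
                self.feature_names_in_[dead],
                "regressors are constant within every group (annihilated by "
                f"the within-transformation): {list(self.feature_names_in_[dead])}",
            )
        xtx = Xd.T @ Xd
        s = np.linalg.svd(xtx, compute_uv=False)
        if s[-1] <= 1e-12 * s[0]:
            raise SingularDesignError(
                self.feature_names_in_,
                "design matrix is collinear after within-transformation "
                f"(columns: {list(self.feature_names_in_)})",
            )
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (Xd.T @ yd)
        resid = yd - Xd @ beta
        rss = float(resid @ resid)
        if self.cov_type == "homoskedastic":
            cov = xtx_inv * (rss / df)
        else:
            meat = np.zeros((k, k))
            for gi in range(g):
                idx = codes == gi
                xe = Xd[idx].T @ resid[idx]
                meat += np.outer(xe, xe)
            correction = (g / (g - 1)) * ((n - 1) / df) if g > 1 else 1.0
            cov = correction * (xtx_inv @ meat @ xtx_inv)

        self.coef_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.df_resid_ = int(df)
        self.n_obs_ = int(n)
        self.n_groups_ = int(g)
        self.resid_ = resid
        xm = np.vstack([np.bincount(codes, weights=X[:, j]) / counts for j in range(k)]).T
        effects = ym - xm @ beta
        self.group_effects_ = dict(zip(uniques, effects))
        self._group_effect_mean_ = float(effects.mean())
        return self

    def conf_int(self, use_t: bool = False) -> np.ndarray:
        """(k, 2) confidence bounds; normal critical value unless ``use_t``."""
        crit = (
            stats.t.ppf(1 - self.alpha / 2, self.df_resid_)
            if use_t
            else stats.norm.ppf(1 - self.alpha / 2)
        )
        half = crit * self.bse_
        return np.column_stack([self.coef_ - half, self.coef_ + half])

    def predict(self, X, groups=None) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        base = X @ self.coef_
        if groups is None:
            return base + self._group_effect_mean_
        effects = np.array(
            [self.group_effects_.get(g, self._group_effect_mean_) for g in groups]
        )
        return base + effects


def within_ols(y, X, groups, cov_type: str = "homoskedastic"
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: within-transformed OLS coefficients and SEs."""
    model = WithinRegressor(cov_type=cov_type).fit(X, y, groups)
    return model.coef_, model.bse_


# ---------------------------------------------------------------------------
# Claims indexing
# ---------------------------------------------------------------------------

def index_claims(claims: pd.DataFrame, adjuster: PriceAdjustment
                 ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-patient ``(months, adjusted_usd)`` arrays, sorted by month."""
    m = month_index_series(claims["month"]).to_numpy()
    usd = (
        claims["expenditure_yen"].to_numpy(float)
        * adjuster.multipliers(m)
        / adjuster.ppp_yen_per_usd
    )
    codes, uniques = pd.factorize(claims["patient_id"])
    order = np.lexsort((m, codes))
    codes, m, usd = codes[order], m[order], usd[order]
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    bounds = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    for chunk in zip(np.split(codes, bounds), np.split(m, bounds), np.split(usd, bounds)):
        out[uniques[chunk[0][0]]] = (chunk[1], chunk[2])
    return out


def _mean_over(months_arr: np.ndarray, usd_arr: np.ndarray,
               wanted: np.ndarray) -> Tuple[float, int]:
    """Mean over ``wanted`` months; months outside observation are dropped,
    observed months missing a claim count as zero."""
    lo, hi = months_arr[0], months_arr[-1]
    inside = wanted[(wanted >= lo) & (wanted <= hi)]
    if len(inside) == 0:
        return float("nan"), 0
    pos = np.searchsorted(months_arr, inside)
    hit = months_arr[np.minimum(pos, len(months_arr) - 1)] == inside
    total = usd_arr[pos[hit]].sum()
    return float(total / len(inside)), len(inside)


# ---------------------------------------------------------------------------
# Matched net estimates
# ---------------------------------------------------------------------------

def matched_net_estimates(
    pairs: pd.DataFrame,
    phase_maps: Dict[str, PhaseMap],
    claims_index: Dict[str, Tuple[np.ndarray, np.ndarray]],
    register: pd.DataFrame,
    treatment_type: str,
    phase: str,
    alpha: float = 0.05,
) -> NetEstimate:
    """Paired case-minus-control net PPPM for one treatment type and phase.

    ``treatment_type`` may be ``"Total"`` to pool all treated cases.  Control
    months are the case's phase months shifted by the pair's anchor offset,
    clipped to the control's observation period.
    """
    cohort = "death" if phase == "terminal" else "incident"
    tt = register.set_index("patient_id")["treatment_type"]
    case_d, control_d = [], []
    skipped = 0
    for _, pair in pairs.iterrows():
        cid = pair["case_id"]
        if treatment_type != TOTAL and tt.get(cid) != treatment_type:
            continue
        pm = phase_maps.get(cid)
        if pm is None:
            continue
        months = np.array(pm.months(phase), dtype=np.int64)
        if len(months) == 0:
            continue
        cm, cu = claims_index[cid]
        case_mean, n_case = _mean_over(cm, cu, months)
        km, ku = claims_index[pair["control_id"]]
        ctrl_mean, n_ctrl = _mean_over(km, ku, months + int(pair["anchor_offset"]))
        if n_case == 0 or n_ctrl == 0:
            skipped += 1
            continue
        case_d.append(case_mean)
        control_d.append(ctrl_mean)
    if not case_d:
        raise EstimationError(
            f"no usable pairs for treatment {treatment_type!r}, phase {phase!r}"
        )
    paired = PairedDifference(alpha=alpha).fit(np.array(case_d), np.array(control_d))
    notes = []
    if paired.degenerate_:
        notes.append("single pair: confidence interval undefined")
    if skipped:
        notes.append(f"{skipped} pairs dropped (no overlapping control months)")
    return NetEstimate(
        method="matched",
        cohort=cohort,
        treatment_type=treatment_type,
        phase=phase,
        net_usd_pppm=paired.mean_,
        ci_low=paired.ci_low_,
        ci_high=paired.ci_high_,
        n=paired.n_,
        reference_usd_pppm=float(np.mean(control_d)),
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# Fixed-effects net estimates
# ---------------------------------------------------------------------------

@dataclass
class FEModelSpec:
    """Which months and covariates enter the within-patient model."""

    cohort: str  # 'incident' (pre + initial + continuing) | 'death' (pre + terminal)
    pre_window: int = DEFAULT_PRE_WINDOW
    covariates: Tuple[str, ...] = ("age", "cci")
    cov_type: str = "homoskedastic"

    @property
    def phases(self) -> Tuple[str, ...]:
        return ("initial", "continuing") if self.cohort == "incident" else ("terminal",)


def fixed_effects_estimates(
    register: pd.DataFrame,
    phase_maps: Dict[str, PhaseMap],
    claims_index: Dict[str, Tuple[np.ndarray, np.ndarray]],
    demographics: pd.DataFrame,
    condition_onsets: pd.DataFrame,
    spec: FEModelSpec,
    treatment_type: str = TOTAL,
    case_ids: Optional[Sequence[str]] = None,
) -> List[NetEstimate]:
    """Within-patient net PPPM per phase for one treatment type and cohort.

    Rows are the case's pre-disease reference months (a ``pre_window``-month
    block ending two months before the index month) plus the cohort's phase
    months.  Each case needs at least one pre month and one phase month.
    ``case_ids`` optionally restricts to specific cases (e.g. matched ones).
    """
    if spec.cohort == "incident":
        flag = "in_incident_cohort"
    elif spec.cohort == "death":
        flag = "in_death_cohort"
    else:
        raise ValueError(f"unknown cohort {spec.cohort!r}")
    cases = register[register[flag]]
    if treatment_type != TOTAL:
        cases = cases[cases["treatment_type"] == treatment_type]
    if case_ids is not None:
        cases = cases[cases["patient_id"].isin(set(case_ids))]

    demo = demographics.set_index("patient_id")
    weights = np.array(CHARLSON_WEIGHTS, dtype=float)

    y_parts, month_parts, group_parts = [], [], []
    phase_parts = {p: [] for p in spec.phases}
    age_parts, cci_parts = [], []
    pre_means = []
    n_cases = 0
    for _, case in cases.iterrows():
        pid = case["patient_id"]
        pm = phase_maps.get(pid)
        if pm is None:
            continue
        index = int(case["index_month"])
        first = int(case["first_observed"])
        pre = np.arange(max(first, index - 1 - spec.pre_window), index - 1)
        months_by_phase = {p: np.array(pm.months(p), np.int64) for p in spec.phases}
        n_phase = sum(len(v) for v in months_by_phase.values())
        if len(pre) == 0 or n_phase == 0:
            continue
        n_cases += 1
        cm, cu = claims_index[pid]
        all_months = np.concatenate([pre] + [months_by_phase[p] for p in spec.phases])
        pos = np.searchsorted(cm, all_months)
        hit = cm[np.minimum(pos, len(cm) - 1)] == all_months
        y = np.where(hit, cu[np.minimum(pos, len(cm) - 1)], 0.0)
        pre_means.append(float(y[: len(pre)].mean()))
        y_parts.append(y)
        month_parts.append(all_months)
        group_parts.append(np.repeat(pid, len(all_months)))
        offset = len(pre)
        for p in spec.phases:
            ind = np.zeros(len(all_months))
            ind[offset : offset + len(months_by_phase[p])] = 1.0
            phase_parts[p].append(ind)
            offset += len(months_by_phase[p])
        birth = month_index(demo.loc[pid, "birth_month"])
        age_parts.append((all_months - birth) // 12)
        onset_row = condition_onsets.loc[pid].to_numpy(np.int64)
        cci_parts.append(
            ((all_months[:, None] >= onset_row[None, :]) * weights[None, :]).sum(axis=1)
        )
    if n_cases == 0:
        raise EstimationError(
            f"no cases with both pre and phase months for {treatment_type!r} "
            f"({spec.cohort} cohort)"
        )

    y = np.concatenate(y_parts)
    groups = np.concatenate(group_parts)
    columns: Dict[str, np.ndarray] = {}
    active_phases = []
    for p in spec.phases:
        col = np.concatenate(phase_parts[p])
        if col.any():
            columns[p] = col
            active_phases.append(p)
    dropped = []
    if "age" in spec.covariates:
        columns["age"] = np.concatenate(age_parts).astype(float)
    if "cci" in spec.covariates:
        columns["cci"] = np.concatenate(cci_parts).astype(float)
    X = pd.DataFrame(columns)
    # Covariates constant within every patient carry no within information;
    # drop them rather than fail the whole model.
    codes, _ = pd.factorize(groups)
    for name in list(X.columns):
        if name in active_phases:
            continue
        col = X[name].to_numpy()
        counts = np.bincount(codes)
        demeaned = col - (np.bincount(codes, weights=col) / counts)[codes]
        if np.abs(demeaned).max() <= 1e-10 * max(1.0, np.abs(col).max()):
            dropped.append(name)
            X = X.drop(columns=[name])

    model = WithinRegressor(cov_type=spec.cov_type).fit(X, y, groups)
    ci = model.conf_int()
    reference = float(np.mean(pre_means))
    notes = f"dropped degenerate covariates: {dropped}" if dropped else ""
    out = []
    names = list(X.columns)
    for p in active_phases:
        j = names.index(p)
        out.append(
            NetEstimate(
                method="fixed_effects",
                cohort=spec.cohort,
                treatment_type=treatment_type,
                phase=p,
                net_usd_pppm=float(model.coef_[j]),
                ci_low=float(ci[j, 0]),
                ci_high=float(ci[j, 1]),
                n=n_cases,
                reference_usd_pppm=reference,
                notes=notes,
            )
        )
    return out
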