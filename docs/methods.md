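# Methods

This note documents the models, conventions, and design choices behind
`phasecost`: what exactly each stage computes, what the synthetic data
generator does and does not emulate, and which decisions were genuinely open.

## 1. Cohorts and phases of care

**Index month.** The first month with an HCC diagnosis flag whose preceding
12 *observed* months carry no cancer diagnosis flag (HCC or other). Patients
younger than 20 in completed years at that month, or observed for fewer than
12 months before their first flag, are ineligible. The 12-observed-month
requirement is deliberately conservative: a patient entering observation 11
months before their first flag cannot demonstrate a clean lookback and is
excluded rather than assumed clean.

**Phase partition.** With index month *i* and death month *d*:

| situation          | initial        | continuing        | terminal        |
|--------------------|----------------|-------------------|-----------------|
| d − i ≥ 8 or alive | {i−1, i, i+1}  | {i+2 … d−6}       | {d−5 … d}       |
| 2 ≤ d − i ≤ 7      | {i−1, i, i+1}  | —                 | {i+2 … d}       |
| d = i + 1          | {i−1, i}       | —                 | {i+1}           |
| d = i              | {i−1}          | —                 | {i}             |

Conventions that the source descriptions leave open, resolved here so the
blocks tile {i−1 … d} with no gap or overlap:

* the terminal window *includes* the death month ("the 6 months before
  death" is read as the 6-month block ending at death, consistent with the
  fixed-effects description of the terminal phase ending in the month of
  death); the continuing phase consequently ends at d−6;
* death one month after the index (not described textually) labels the death
  month terminal by analogy with death during the index month;
* "death within 7 months of the index" is read as d − i ≤ 7 — the largest
  offset at which the standard rule would leave an empty continuing block;
* for censored patients (no observed death) the initial block is clipped to
  the last observed month and the continuing phase runs to the end of
  observation; phases never extend past observation.

An exhaustive brute-force check over all death offsets 0–60 (and a property
test over larger offsets) verifies the partition.

**Recurrence.** A case is excluded as recurrent HCC when some diagnosis month
is preceded by ≥ 7 consecutive months without any anticancer-therapy flag,
counting only months after the last treated month of the initial window (or
after the first treated month when therapy started later). Because claims
carry a diagnosis flag every month a patient is under care, this operates as
a treatment-gap rule, which is how it is detectable in claims at all.

**Treatment types.** The modality set observed from one month before the
index through death/censoring maps onto 16 categories (4 resection rows, 4
locoregional-therapy rows, TACE/TAE/sorafenib combinations, and a residual
"Others"). The mapping is total over all 2⁷ modality subsets (tested by
enumeration): resection takes precedence, then LRT; "+ others" rows absorb
any extra modality beyond the named pair; combinations without a named row
fall into "Others". Cases with no observed anticancer modality are excluded
(only treated patients are analysed). The window and the precedence order are
package conventions; the sources name the categories but not the assignment
algorithm.

## 2. Matching

The match key is (sex, 5-year age band, 15 Charlson condition flags). Age
bands are 20–24 … 90–94, 95+; each participant's band and flags are
evaluated at their own anchor month. Condition flags are onset-only (no
remission), so "flag state over the 12 months ending at the anchor" equals
"first flagged month ≤ anchor", which is what the matcher uses for both cases
and controls.

Incident matching anchors on the case's index month and requires the control
to have utilization (positive expenditure) in the anchor month; when the
stratum is empty the window expands month by month up to ±12, trying the
earlier of two equidistant months first (deterministic, and pre-index months
cannot be contaminated by later secular trends). Death matching requires the
identical death month with no expansion. Controls have no HCC flag anywhere
in their history, are drawn uniformly at random with a seeded generator, and
are removed from the pool once used. Cases are processed in ascending
patient-id order (any fixed order works; this one is reproducible). Unmatched
cases are written to a report, never dropped silently.

## 3. Estimators

All expenditures are deflated per service month and converted to USD at
102.5 yen/USD before estimation; estimates are therefore in constant-price
USD PPPM. Months with no utilization count as zeros wherever they are within
a patient's observation period; months outside observation (after death, or
the unobservable month following a diagnosis at the very end of the study
window) are excluded from denominators, not zero-filled — zero-filling them
would bias phase means toward zero.

**Matched comparison.** For a pair j, d_j = (case PPPM over its phase months)
− (control PPPM over the same months shifted by the pair's anchor offset,
clipped to the control's observation). The cell estimate is d̄ with the
paired-t 95% interval d̄ ± t₀.₉₇₅,ₙ₋₁·s/√n. Pairs whose control contributes
no overlapping months are dropped and counted in the estimate's notes; a
single-pair cell is flagged with an undefined CI.

**Within (fixed-effects) estimator.** `WithinRegressor` demeans outcome and
regressors within patient, runs OLS on the demeaned data, and corrects the
residual degrees of freedom to n − G − k. This is numerically identical to
OLS with one indicator per patient (verified against a patient-dummy
regression to 1e-8 relative tolerance on random panels). Standard errors are
conventional homoskedastic OLS by default; cluster-robust (by patient, with
the usual G/(G−1)·(n−1)/df correction) is available via `cov_type="cluster"`
since the variance estimator of the original analysis is unstated.
Regressors that the within-transformation annihilates raise a
`SingularDesignError` naming the columns.

**Model per treatment type and cohort.** Rows are each case's pre-disease
reference months — the 12-month block ending at index−2, because index−1
already belongs to the initial phase; the window length is configurable —
plus the cohort's phase months (incident: initial + continuing; death:
terminal). Phase indicators enter with the pre months as reference; phase
coefficients with coefficient ± 1.96·SE intervals are the net estimates, and
the mean adjusted expenditure over pre months is reported as the reference
level. Covariates are time-dependent age in completed years and the Charlson
score, recomputed monthly from the condition flags with the original weights
(1 for most conditions; 2 for diabetes with complications, hemiplegia, renal
disease; 3 for moderate/severe liver disease; 6 for AIDS). A covariate that
is constant within every patient in a stratum (e.g., the Charlson score when
no condition onsets occur) carries no within-information and is dropped with
a note on the estimate rather than failing the model; the phase indicators
are never dropped.

A longer pre-window than the single "preceding month" stabilizes the within
estimator considerably at no cost to identification; 12 months uses exactly
the clean cancer-free lookback that eligibility already guarantees.

## 4. Price adjustment

Fiscal years run April–March. Revision rates relative to 2018 prices:
1.019 (FY2010–11), 1.004 (FY2012–13), 1.1001 (FY2014–15), 0.9916
(FY2016–17). The FY2014–15 value is implausibly large next to its
neighbours and may be a misprint of 1.001; the printed value is the default
and the whole map is overridable in the run config. Order of operations:
deflate in yen per service month, aggregate, convert to USD once — the two
operations commute multiplicatively, so the order is a reporting convention,
not a numerical one.

## 5. Synthetic claims generator

One row per patient-month from the study start until death or the study end.
Per patient: sex, an age band (5-year bands; age then advances monthly),
baseline Charlson flags drawn per-condition from configurable prevalences
(optionally with a monthly onset hazard afterwards), and a baseline mean
expenditure μ_i = baseline_mean × a^(band index) × c^(condition count),
normalized so the population mean equals `baseline_mean_yen` exactly in
expectation. Monthly expenditure is gamma(shape k, mean μ_i), independent
across months given μ_i — right-skewed and non-negative, the minimal
realistic cost shape. HCC onset follows a constant monthly hazard; death a
background hazard that switches to a post-HCC hazard from onset. Cases carry
the diagnosis flag from onset onward, receive the full modality set of their
sampled treatment type in the first months and maintenance re-administration
of one modality with a configurable monthly probability afterwards (which
keeps most treated survivors clear of the recurrence rule, while a realistic
minority with long gaps is excluded by it). Injected incremental costs are
added in the months of each case's true phase (classified by the same rules
the pipeline uses). In the last k months of every decedent's life — HCC or
not — the baseline component is multiplied by the end-of-life surge factor;
this common surge is precisely the mechanism that drives the terminal-phase
divergence between the two estimators, and it is the generator's key lever.
Finally, each month is independently zeroed with probability
`zero_utilization_prob` (a no-claims month), which scales the per-month
estimand of *both* estimators to (1−z)·increment.

Default parameter choices (overridable in `SimulationConfig`): baseline mean
65,000 yen/month with gamma shape 2 (pre-disease reference levels around
$630 PPPM), age distribution concentrated in the 50s–80s, 35% female,
treatment mix matching the published national case mix, injected increments
380k/30k/310k yen per month for initial/continuing/terminal (the magnitudes
of national per-phase net estimates), post-HCC death hazard 0.03/month
(median survival around two years), background death hazard 0.003/month,
end-of-life surge ×3 over the last 6 months, 10% zero-utilization months.

What the generator does **not** emulate: fee-schedule itemization and price
revisions (costs are injected at a constant price level, so synthetic-panel
analyses use an identity deflator with only the PPP conversion); provider-
level claim splitting; staggered enrolment (everyone enters at the study
start); expenditure–mortality dependence beyond the end-of-life surge;
disease staging, progression, or cost trajectories within a phase; seasonal
or secular trends. Passing recovery tests therefore show that the estimators
recover additive phase costs under exact matching and a stationary baseline —
not that either method is unbiased under confounding structures the
generator does not contain (e.g., expenditure-predictive characteristics
outside the match key).

## 6. Simulation scenarios

`phasecost.scenarios` fixes three named study conditions used by the tests
and the acceptance script:

* **recovery** — injected increments as above, no surge, no zero-utilization
  months (so the injected increment is the estimand itself rather than
  (1−z)·increment), static condition flags, ~6,000 patients over 60 months
  yielding roughly 500 eligible incident cases and 300 death-cohort cases per
  panel. Both estimators' 95% CIs cover the injected truth per phase, and the
  mean bias across 50 seeded replicates is well under 5% of the truth
  (observed |bias| ≲ 0.5%).
* **divergence** — zero injected increments, a common end-of-life surge over
  the last 6 months of every decedent, surge multiplier on a {1, 2, 3} grid,
  death cohort only. The fixed-effects terminal estimate exceeds the matched
  one in essentially all replicates at multiplier 3, and the mean gap grows
  monotonically with the multiplier (≈$0 at 1, ≈$450 at 2, ≈$900 at 3 in
  constant-price USD PPPM).
* **null** — no injected effects, no surge, homogeneous baseline means.
  Fixed-effects phase-coefficient 95% CIs contain zero at the nominal rate
  (200-replicate coverage within the binomial 91–98% band).

Panel sizes in the scenarios (and the smaller replicate counts used by
`scripts/acceptance.py`) are the package's desk-scale choices: large enough
that sampling noise does not mask estimator bias of the size worth caring
about, small enough to run on one CPU in minutes.

## 7. Numerical and degenerate-input conventions

* Months are integer indices internally (`YYYY-MM` externally); all windows
  are closed integer ranges.
* Exact matching ties are broken uniformly at random with a caller-supplied
  seed; expansion ties prefer the earlier month.
* `WithinRegressor` flags singularity via the minimum singular value of the
  demeaned Gram matrix (relative tolerance 1e-12) and zero within-variance
  columns (1e-10 relative); estimation with n − G − k ≤ 0 raises.
* PPPM over an empty month set is an error, never silently zero; the
  proportional difference with a zero fixed-effects denominator is an error
  in scalar form and NaN in table form.
* The generator rounds expenditures to 0.01 yen for CSV stability; identical
  configs and seeds reproduce byte-identical CSVs.

## 8. Known limitations

* Exact matching on 17 variables needs large control pools; at desk scale
  the death cohort's same-month requirement leaves a substantial unmatched
  fraction (reported, never silently dropped). This mirrors the real
  design's behaviour, where matched and unmatched cases differ
  systematically — estimates generalize to the matchable, not to all cases.
* The incident-cohort utilization requirement conditions the control's
  anchor month on being non-zero, which with zero-utilization months in
  play shifts that single month's expectation slightly; with 10% zero
  months and 3-month phase windows the effect on the initial-phase estimate
  is well under the estimators' sampling noise at desk scale.
* Homoskedastic FE standard errors understate uncertainty when baseline
  means are heterogeneous (gamma variance scales with μ²); cluster-robust
  errors are provided for that case.
* The recurrence rule depends on therapy flags only; a patient whose
  maintenance therapy is simply undocumented is indistinguishable from a
  recurrence.
* No two-part/hurdle or gamma-log cost models: the estimands are arithmetic
  means, as in the designs this package implements.
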