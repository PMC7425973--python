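# phasecost

Phase-of-care healthcare expenditure attribution for hepatocellular carcinoma
(HCC) from longitudinal claims panels.

Health economists estimating the incremental cost of a disease from
administrative claims usually reach for one of two designs: a **matched
case–control comparison** (subtract the expenditure of an exactly matched
non-diseased control) or a **within-patient fixed-effects regression** (let
each patient act as their own pre-disease control). The two designs can
disagree — most dramatically in the terminal phase of care, where everyone's
expenditure surges before death whether or not they have the disease of
interest. This package implements both estimators, the phase-of-care cohort
machinery around them, their comparison statistics, and a synthetic claims
generator with known injected costs so every stage is verifiable without
access to restricted national claims data.

## The estimands and methods

For each treatment type *t* and phase of care *p* ∈ {initial, continuing,
terminal}, the target is the disease-associated expenditure **per patient per
month (PPPM)** in price-adjusted USD.

* **Phases.** The initial phase is the 3-month window {index−1, index,
  index+1} around the first qualifying HCC diagnosis month (after a 12-month
  cancer-free lookback, adults ≥ 20); the terminal phase is the 6-month window
  ending at the death month; the continuing phase is everything in between.
  Deaths within 7 months of the index collapse the pattern (no continuing
  phase; the death month is always terminal). Recurrent HCC — a new diagnosis
  after ≥ 7 consecutive months without anticancer therapy — is excluded.
* **Matched comparison.** Each case is matched, without replacement, to one
  control with identical sex, 5-year age band and 15 Charlson condition flags
  (malignancies excluded), anchored on the index month (incident cohort; the
  anchor window expands up to ±12 months if needed) or on the exact death
  month (death cohort). The estimate for a cell is the mean of paired
  differences d̄ = mean(case PPPM − control PPPM) with a Student-t 95% CI.
* **Fixed-effects analysis.** On patient-month rows (pre-disease reference
  months plus phase months, zero-utilization months kept as zeros), the
  within estimator regresses monthly expenditure on phase indicators plus
  time-dependent age and Charlson score after demeaning within patient:
  the phase coefficients are the net estimates,
  y_it = α_i + Σ_p β_p·phase_p(it) + γ·age_it + δ·CCI_it + ε_it.
* **Comparison statistics.** proportional difference = 1 − matched/FE;
  absolute difference = FE − matched.
* **Price adjustment.** Expenditures are deflated per service month with the
  fee-schedule revision rates relative to 2018 (1.019 for FY2010–11, 1.004
  for FY2012–13, 1.1001 for FY2014–15, 0.9916 for FY2016–17; fiscal years run
  April–March), then converted once at the purchasing-power-parity rate of
  102.5 yen per USD.

## Worked example 1: the published method-divergence figures

The package ships the published per-phase net estimates of a nationwide
Japanese HCC claims study as a benchmark table; the comparison statistics
recompute that study's headline differences:

```python
from phasecost import published_comparison

cmp = published_comparison()
cmp["prop_pct"] = (100 * cmp.proportional_difference).round(1)
print(cmp[cmp.treatment_type == "Total"][
    ["phase", "matched", "fixed_effects", "prop_pct", "absolute_difference"]
])
```

```
      phase  matched  fixed_effects  prop_pct  absolute_difference
 continuing      305            285      -7.0                  -20
    initial     3353           3684       9.0                  331
   terminal      208           3026      93.1                 2818
```

Initial- and continuing-phase estimates agree within roughly ±10% between the
methods, but the terminal-phase fixed-effects estimate is 93.1% (=$2,818
PPPM) higher than the matched one — the divergence this package's simulation
reproduces mechanistically (see below).

## Worked example 2: recovering known costs from a synthetic panel

```python
from phasecost.scenarios import recovery_config, analyze_panel

res = analyze_panel(recovery_config(seed=0))   # ~6,000 patients, 60 months
print(res["truth_usd"])                        # injected costs, USD PPPM
for e in res["estimates"]:
    print(e.method, e.phase, e.n, round(e.net_usd_pppm, 1),
          (round(e.ci_low, 1), round(e.ci_high, 1)))
```

```
{'initial': 3707.3, 'continuing': 292.7, 'terminal': 3024.4}
matched        initial    488  3689.1  (3653.4, 3724.8)
matched        continuing 286   290.1  (251.2, 328.9)
fixed_effects  initial    488  3681.3  (3653.0, 3709.6)
fixed_effects  continuing 488   304.6  (272.7, 336.6)
matched        terminal   189  3040.2  (2986.7, 3093.7)
fixed_effects  terminal   189  3070.6  (3011.3, 3130.0)
```

Both estimators' 95% CIs cover the injected truth in every phase. Turning on
the generator's common end-of-life surge (a multiplier on every decedent's
baseline expenditure in their last 6 months, HCC or not) leaves the matched
terminal estimate unchanged — the control dies the same month and surges too
— while the fixed-effects estimate absorbs the whole surge, reproducing the
terminal-phase divergence direction.

## Command line

```bash
phasecost simulate --config config.yaml --out run/   # synthetic panel CSVs
phasecost run-all  --config config.yaml --out run/   # full chain + manifest
# or stage by stage into the same directory:
phasecost classify --config config.yaml --out run/
phasecost match    --config config.yaml --out run/
phasecost estimate --config config.yaml --out run/
phasecost compare  --config config.yaml --out run/
phasecost validate run/claims.csv
```

`run-all` writes `claims/demographics/truth` (when simulating),
`phase_map.csv`, `case_register.csv`, `pairs.csv`, `unmatched.csv`,
`estimates.csv` (per method × cohort × treatment type × phase),
`comparison.csv`, and a `manifest.json` with seeds, a config hash and
per-stage record counts. Identical config and seeds give byte-identical
outputs.

## Layout

```
src/phasecost/
  simulate.py     seeded synthetic claims generator (+ injected ground truth)
  phases.py       index-month finding, recurrence exclusion, phase maps,
                  treatment typing
  matching.py     ExactMatcher, incident/death cohort construction
  estimators.py   WithinRegressor, PairedDifference, PPPM, net estimates
  adjust.py       price revision, PPP conversion, comparison statistics
  scenarios.py    named simulation scenarios used by tests and acceptance
  pipeline.py     staged orchestration, validation, manifest
  cli.py          click CLI
  published.py    published benchmark estimates (worked-example inputs)
```

The statistical core follows scikit-learn conventions (`fit`,
`get_params`/`set_params`, fitted attributes with trailing underscores), so
`WithinRegressor` composes with sklearn tooling; module-level functions such
as `within_ols` and `match_incident` are thin wrappers. See
`docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
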