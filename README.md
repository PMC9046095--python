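# ep-routes

Tools for analysing **emergency presentation (EP)** as a route to cancer
diagnosis from linked cancer-registry and hospital-admissions data, and for
pooling jurisdiction-level results the way a federated, aggregate-only
international comparison does.

A diagnosis is an emergency presentation when it occurs within 30 days
after an emergency hospital inpatient admission.  EP is common (roughly a
quarter to two-fifths of diagnoses for the eight cancer sites covered
here), strongly patterned by cancer site, age and stage, and carries a
large short-term mortality penalty even after stage adjustment — which
makes between-jurisdiction differences in EP frequency a candidate
explanation for international cancer-survival gaps.  The package is
aimed at cancer-registry analysts and epidemiologists who want to
compute EP measures locally and share only aggregates.

## What it computes

- **Classification** — per patient, from diagnosis date and an admission
  history: *broad* EP (some emergency admission within the window,
  boundary days inclusive) and *narrow* EP (additionally, no elective
  admission strictly between the emergency admission and diagnosis).
  The window defaults to 30 days and is configurable (60/90-day
  sensitivity analyses).
- **Cohort rules** — ages 15–99, invasive tumours (behaviour code 3) of
  oesophagus (ICD-10 C15), stomach (C16), colon (C18–19), rectum (C20),
  liver (C22), pancreas (C25), lung (C34) and ovary (C48.1–2, C56,
  C57.0), excluding borderline ovarian morphologies (ICD-O-3 8442, 8451,
  8462, 8472, 8473).
- **Descriptives** — stratified EP percentages with Wilson score
  intervals; cross-jurisdiction concordance of the site ordering
  (pairwise Pearson *r* against a reference jurisdiction).
- **Odds ratios** — closed-form 2×2 ORs with Woolf standard errors, and
  multivariable logistic models: EP risk on site + age group + sex +
  year (± stage), and mortality at 1/3/12 months (censored-before-horizon
  counted as alive) on EP status plus the same covariates.
- **Meta-analysis** — random-effects pooling of jurisdiction log-ORs,
  `y_i = β₀ + β₁·narrowᵢ + uᵢ + eᵢ`, with `uᵢ ~ N(0, τ²)` estimated by
  REML (default) or DerSimonian–Laird, inverse-variance weights
  `1/(vᵢ+τ²)`, Cochran's Q and I².  The broad/narrow definition type is
  the moderator; per-definition pooled ORs are the fitted values at each
  moderator level.
- **Ecological regression** — unweighted OLS of jurisdiction-level
  1-year net survival (an external input) on EP percentage plus a
  narrow-definition indicator; the slope is reported per 10 percentage
  points of EP.
- **Federated contract** — `run_jurisdiction` executes the local
  pipeline and emits an aggregate-only bundle (small cells suppressed,
  patient-level columns forbidden by schema); `collate` merges bundles
  into the central tables.
- **Synthetic registry** — a configurable generator for linked
  tumour/admission tables with known EP and mortality models, so every
  stage is testable end-to-end without real registry data.

## Worked example

```python
import ep_routes as ep
from ep_routes.published import (
    mortality_table, stage_adjusted_study_estimates, ep_percentage_matrix,
)

# crude 12-month mortality OR from printed counts (Denmark)
r = mortality_table().set_index("jurisdiction").loc["Denmark"]
est = ep.crude_or(r.deaths_ep, r.n_ep - r.deaths_ep,
                  r.deaths_non_ep, r.n_non_ep - r.deaths_non_ep)
print(round(est.or_, 2))                      # 3.88

# REML meta-regression of the 12 stage-adjusted ORs, definition moderator
res = ep.pool_random_effects(stage_adjusted_study_estimates(), moderator=True)
print(round(res.pooled["broad"].or_, 2))      # 2.86
print(round(res.pooled["narrow"].or_, 2))     # 3.09
print(round(res.i2_tau2))                     # 93

# site-ordering concordance vs the largest jurisdiction
conc = ep.site_order_concordance(ep_percentage_matrix(), "England")
print(round(min(conc.values()), 2))           # 0.88
```

The crude OR is the mortality contrast between emergency and
non-emergency presenters before any adjustment; the pooled values say
that, after adjusting for site, age, sex, year and stage, emergency
presenters have about three times the odds of dying within 12 months of
diagnosis, with substantial between-jurisdiction heterogeneity
(I² ≈ 93%) but a consistent direction everywhere; the concordance shows
that which cancers are most often diagnosed as emergencies is nearly the
same ordering in every jurisdiction.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study on synthetic data
and the published aggregates, writing tables to `results/` (patient-level
synthetic data and figures go to `scratch/`):

```bash
python analysis/01_simulate_cohorts.py --seed 0
python analysis/02_classify_emergency_presentations.py
python analysis/03_descriptive_summaries.py
python analysis/04_association_models.py
python analysis/05_meta_analysis.py
python analysis/06_ecological_regression.py --seed 0
```

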