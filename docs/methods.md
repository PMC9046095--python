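# Methods

## The measure

Emergency presentation (EP) is operationalised from linked registry and
inpatient-admissions records: a diagnosis is **broad-EP** when at least
one *emergency* admission falls within `window_days` (default 30) before
the diagnosis date, both boundary days inclusive, and **narrow-EP** when
some qualifying emergency admission has no elective admission strictly
between it and the diagnosis.  The definitions are contextual, not
clinical: only dates and the emergency/elective admission type are used,
never admission diagnosis codes.  Three boundary conventions matter and
are fixed as follows:

- a same-day admission and diagnosis counts as EP (offset 0 is inside
  the window) — diagnoses commonly happen during the index admission;
- an elective admission on the same calendar day as the emergency
  admission or as the diagnosis is *not* intervening: day-granularity
  data cannot order same-day events, so strict inequalities are used;
- the anchor is the *latest* qualifying emergency admission.  For the
  narrow rule this is sufficient as well as convenient: any elective
  intervening for the latest qualifying emergency also intervenes for
  every earlier one, so "some anchor works" reduces to "the latest
  anchor works".  The test suite verifies this against brute-force
  enumeration over all ≤3-admission histories on an offset grid.

Admission date (not discharge date) anchors the emergency episode; the
source reports do not state which was used, and admission date is the
field registries most reliably hold.

## Cohort rules

Ages 15–99 at diagnosis (evaluated on the grouped age variable; a raw
age column, when present, is banded first), invasive tumours (behaviour
code 3) of the eight sites, borderline ovarian morphologies excluded,
diagnosis year inside the study period (2012–17 by default).  Records
failing several rules are counted once under a fixed precedence
(missing diagnosis date → unmappable site → age → behaviour →
borderline morphology → year); precedence affects only the reported
reason tallies, never membership of the included set.  ICD-10 codes are
accepted dotted or undotted at 3- or 4-character precision; C48 and C57
map to the ovarian group only through the listed sub-codes (C48.1–2,
C57.0).

## Models

**Percentages.**  Stratified EP percentages carry Wilson score 95%
intervals (z = Φ⁻¹(0.975) ≈ 1.959964, no continuity correction); Wilson
is used because it stays inside [0, 1] at extreme counts.  Rounding to
one decimal happens only at presentation; internal values keep full
precision.

**Logistic models.**  EP risk: model 1 on site + age group + sex + year
of diagnosis; model 2 adds stage.  Mortality at 1, 3 and 12 months
(30/91/365 days — calendar-month conventions vary, these are the registry
day counts): crude (EP only), adjusted without stage, stage-adjusted.
Patients censored before a horizon count as alive at it, which is
defensible when registry loss to follow-up is negligible, and is the
reason plain logistic regression is used rather than a censoring-aware
survival model.  Categorical covariates are treatment-coded with
references colon (site), 15–64 (age), female (sex), earliest year, stage
1, non-EP; year is categorical since no linearity is assumed.  Missing
stage enters stage-adjusted models as an explicit category by default
(a complete-case flag exists); this preserves cohort size at the cost of
a hard-to-interpret "missing" coefficient.  Wald CIs match the symmetric
intervals aggregate reports print.  Perfect separation and rank
deficiency raise loud errors; in the per-jurisdiction batch they are
recorded as flagged rows rather than aborting the run.  Zero cells in
2×2 tables are an error, not a silent continuity correction.

**Random-effects pooling.**  On the log-OR scale,
`y_i = x_i'β + u_i + e_i`, `u_i ~ N(0, τ²)`, `e_i ~ N(0, v_i)` with `v_i`
the squared within-jurisdiction SE (back-derived from printed CIs as
`(ln U − ln L)/(2z)` when pooling published tables).  The design is an
intercept plus, when the moderator is on, a narrow-definition indicator;
per-definition pooled ORs are the fitted values at each moderator level
with delta-method CIs.  τ² is estimated by REML (profiled restricted
likelihood, bounded scalar optimisation, boundary at 0 checked
explicitly) or by the DerSimonian–Laird moment estimator in its
meta-regression form `τ² = max(0, (Q_E − (k−p))/tr(P))`.  Heterogeneity
is reported two ways: `i2`, the Q-based `max(0, (Q−df)/Q)·100`, and
`i2_tau2`, the τ²-based `100·τ²/(τ²+s²)` with `s² = (k−p)/tr(P)` — the
form standard meta-analysis software prints, and the one that
corresponds to the reported ≈93% residual heterogeneity.  The
implementation is cross-checked in the tests against an independent
metafor (R) fit frozen to 4+ decimals.  Knapp–Hartung adjustment is off
by default (nothing indicates it was used in the source analyses).

**Ecological regression.**  Per cancer site, unweighted OLS of
jurisdiction-level 1-year net survival on EP percentage and a
narrow-definition indicator (dropped automatically when only one
definition type is present).  Slopes are reported per 10 percentage
points; p-values are two-sided from the t distribution.  Net survival
is strictly an input: the package never estimates it.  Precision
weighting of the survival estimates was deliberately not added — the
replicated analysis is an ordinary linear regression — and an exact fit
(zero residuals) returns a degenerate CI at the point estimate rather
than dividing by a zero residual variance.

**Federated contract.**  A jurisdiction bundle contains stratum
summaries and model estimates only; a schema scan rejects any
patient-level column.  Cells whose numerator or complement is positive
but below the suppression threshold (default 5, configurable to 0 for
synthetic data) are masked before export, and masked cells are excluded
from central consistency checks with a flag.  Collation refuses to pool
bundles computed at different window lengths.

## The synthetic registry

The generator emulates the *structure* the analysis needs, not any real
population: per jurisdiction, covariates (site, age group, sex, latent
4-level stage) are drawn independently from configured mixes; a latent
EP indicator follows a logistic model on them (plus a per-jurisdiction
intercept shift so jurisdictions span a realistic EP range, roughly
24–42% observed internationally); admission histories are built to
match the latent status (broad-EP: one emergency admission uniform 0–30
days pre-diagnosis; with probability `narrow_discordance` — default
0.16, putting the broad-minus-narrow gap near the ~5 percentage points
reported where both definitions were computed — also an elective
admission strictly between; for those cases the emergency offset is
drawn on 2–30 days so a strictly-between day exists); 12-month death is
Bernoulli from a logistic model including an EP log-OR of ln 3, with the
death date uniform on (diagnosis, diagnosis+365] and survivors censored
at diagnosis+400 days.  A binary death indicator suffices because the
analysis only uses mortality at fixed horizons.  Small fractions of
non-EP patients receive an in-window elective admission (1%) or an
emergency admission 31–120 days pre-diagnosis (5%) to exercise the
type and window boundaries.  Observed stage is a registry artifact of
the latent truth: optionally collapsed to 3 levels, missing at random at
a configurable rate, or absent entirely (emulating registries without
stage across all sites, whose stage-adjusted models are skipped with a
flag).

Default mixes (lung- and colon-dominated site mix, male excess, ~10%
unstaged) are loosely shaped on large-registry composition and are
config values, not claims.  Everything is deterministic given the seed,
to the byte in the CSV outputs.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: correlated covariates (independence is a
modelling convenience; real site/age/stage are strongly associated),
full admission histories, comorbidity, screening detection,
jurisdiction-specific coding practice, and between-jurisdiction
heterogeneity in the true EP-mortality effect (the generating
conditional OR is common, so synthetic I² is small, unlike the ≈93%
in the real aggregates).

## Calibration and replication checks

The acceptance layer distinguishes what can be replicated from print and
what can only be validated by simulation.  Printed-input replications:
EP percentages and mortality proportions from numerator/denominator
pairs; crude ORs from 2×2 counts (two Statistics-Canada jurisdictions
differ at the second decimal because their printed counts are
disclosure-rounded to multiples of 5); REML pooled broad/narrow ORs from
the 12 stage-adjusted estimates; minimum site-ordering concordance
(computed from 1-dp rounded percentages, it agrees with the published
minimum at its printed precision).  Simulation-validated: the ecological
betas (the external net-survival inputs and exact 17-jurisdiction EP
percentages are not public), checked instead by exact noiseless recovery
and ~95% CI coverage over 200 replicates; and parameter recovery of the
generating logistic coefficients and pooled OR at nominal coverage,
using 200 replicates of n = 3000 with pre-specified binomial tolerance
bands (±3.5 binomial SDs around 0.95).  Problem sizes in the routine
suite (3000–20,000 patients per jurisdiction, 50,000 for single-fit
recovery) keep each run to seconds while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- Odds ratios are non-collapsible: the crude EP-mortality OR is not the
  stage-adjusted one even without confounding, and marginal ORs from the
  generator are attenuated relative to the conditional ln 3.
- The "missing" stage category assumes missingness carries no outcome
  information beyond the category itself.
- The ecological stage inherits all the usual caveats of population-level
  regression: 14–17 points, no within-jurisdiction contrast, and no
  causal reading.
- The federated layer implements the aggregate-only *contract*, not a
  distributed execution framework: no networking, no secure computation.
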