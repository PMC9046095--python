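"""Logistic-regression machinery: EP-risk models, EP-mortality models at
fixed horizons, and closed-form 2x2 odds ratios.

Mortality is all-cause observed mortality at 1, 3 and 12 months from
diagnosis (30 / 91 / 365 days).  Patients censored before a horizon are
assumed alive at it — defensible where registry loss to follow-up is
negligible — which is why plain logistic regression, not a censoring-
aware survival model, is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

HORIZON_DAYS = {"1m": 30, "3m": 91, "12m": 365}

_Z95 = stats.norm.ppf(0.975)

MORTALITY_OUTCOMES = tuple(f"death_{h}" for h in HORIZON_DAYS)

DEFAULT_REFERENCES = {
    "site": "colon",
    "age_group": "15-64",
    "sex": "female",
    "stage": "1",
}

_COVARIATE_COLUMNS = {
    "ep_status": "ep",
    "site": "site",
    "age_group": "age_group",
    "sex": "sex",
    "year": "year",
    "stage": "stage",
}


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


class AliasedTermError(RuntimeError):
    """Design matrix is rank deficient; some term is aliased."""


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome to model on which covariates.

    ``outcome`` is ``"ep"`` or one of ``death_1m/death_3m/death_12m``;
    ``covariates`` use analysis names (``ep_status`` for the exposure).
    """

    outcome: str
    covariates: tuple[str, ...]
    reference_levels: dict = field(default_factory=dict)
    stage_adjusted: bool = False

    def __post_init__(self):
        valid = ("ep",) + MORTALITY_OUTCOMES
        if self.outcome not in valid:
            raise ValueError(f"outcome must be one of {valid}")
        unknown = set(self.covariates) - set(_COVARIATE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if "ep_status" in self.covariates and self.outcome == "ep":
            raise ValueError("ep_status is only a covariate for mortality outcomes")


@dataclass
class EffectEstimate:
    """One exponentiated coefficient with its Wald CI."""

    term: str
    log_or: float
    se: float
    jurisdiction: str | None = None
    model: str | None = None

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - _Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + _Z95 * self.se)


def mortality_indicator(record, horizon: str) -> bool:
    """Death on or before diagnosis + horizon days (censored => alive)."""
    days = HORIZON_DAYS[horizon]
    death = record["death_date"]
    if pd.isna(death):
        return False
    delta = (death - record["diagnosis_date"]).days
    if delta < 0:
        raise ValueError(f"death before diagnosis for {record.get('patient_id', '?')}")
    return delta <= days


def add_mortality_indicators(tumours: pd.DataFrame) -> pd.DataFrame:
    """Vectorised death_1m / death_3m / death_12m boolean columns."""
    df = tumours.copy()
    delta = (df["death_date"] - df["diagnosis_date"]).dt.days
    if (delta < 0).any():
        bad = df.loc[delta < 0, "patient_id"].tolist()[:5]
        raise ValueError(f"death before diagnosis for patient(s) {bad}")
    for h, days in HORIZON_DAYS.items():
        df[f"death_{h}"] = delta.notna() & (delta <= days)
    return df


def crude_or(a: int, b: int, c: int, d: int) -> EffectEstimate:
    """Odds ratio from a 2x2 table: exposed dead/alive = a/b, unexposed = c/d.

    OR = ad/bc with Woolf SE of the log-OR, sqrt(1/a+1/b+1/c+1/d).  Any
    zero cell raises — no continuity correction is applied silently.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if any(x == 0 for x in cells):
        raise ZeroDivisionError("zero cell in 2x2 table; odds ratio undefined")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(term="exposure", log_or=log_or, se=se, model="crude")


def _term_expr(cov: str, data: pd.DataFrame, references: dict) -> str:
    col = _COVARIATE_COLUMNS[cov]
    if cov == "ep_status":
        return "C(ep, Treatment(False))"
    if cov == "year":
        ref = references.get("year", int(data["year"].min()))
        return f"C(year, Treatment({ref}))"
    ref = references.get(col, DEFAULT_REFERENCES.get(col))
    return f"C({col}, Treatment('{ref}'))"


def _pretty_term(raw: str) -> str:
    # "C(site, Treatment('colon'))[T.lung]" -> "site=lung"
    if "[T." not in raw:
        return raw
    head, level = raw.split("[T.", 1)
    level = level.rstrip("]")
    var = head.split("(", 1)[1].split(",")[0].strip()
    if var == "ep":
        var = "ep_status"
    return f"{var}={level}"


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> list[EffectEstimate]:
    """Maximum-likelihood logistic fit with treatment-coded categoricals.

    References: colon (site), 15-64 (age group), female (sex), earliest
    year, stage 1, non-EP.  Returns one estimate per non-reference level
    with Wald standard errors.
    """
    refs = dict(spec.reference_levels)
    terms = [_term_expr(c, data, refs) for c in spec.covariates]
    formula = f"I({spec.outcome} * 1) ~ " + " + ".join(terms)
    try:
        with np.errstate(all="ignore"):
            res = smf.logit(formula, data=data).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise ConvergenceError(str(e)) from e
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge (possible separation)")
    if np.isnan(res.bse.drop("Intercept", errors="ignore")).any():
        raise AliasedTermError("rank-deficient design: aliased term(s)")
    out = []
    for raw, coef, se in zip(res.params.index, res.params, res.bse):
        if raw == "Intercept":
            continue
        out.append(EffectEstimate(term=_pretty_term(raw), log_or=float(coef), se=float(se)))
    return out


def _estimates_to_rows(estimates, jurisdiction, model, horizon, n, definition):
    return [
        {
            "jurisdiction": jurisdiction,
            "model": model,
            "horizon": horizon,
            "term": e.term,
            "log_or": e.log_or,
            "se": e.se,
            "or": e.or_,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n": n,
            "definition": definition,
            "converged": True,
            "note": "",
        }
        for e in estimates
    ]


def run_jurisdiction_models(
    labelled: pd.DataFrame,
    horizons: tuple[str, ...] = ("1m", "3m", "12m"),
    definition: str = "broad",
    complete_case_stage: bool = False,
) -> pd.DataFrame:
    """Fit the full model battery for every jurisdiction in the table.

    Per jurisdiction: EP-risk model 1 (site + age group + sex + year) and
    model 2 (+ stage); and, per horizon, mortality models crude (EP only),
    adjusted-without-stage, and stage-adjusted.  ``labelled`` must carry
    site/age_group/sex/year/stage, death indicators, and the chosen EP
    definition column (copied into ``ep``).  Missing stage is an explicit
    "missing" category unless ``complete_case_stage``.  Jurisdictions
    without any stage data get their stage-adjusted models skipped with a
    flag row rather than aborting the batch.
    """
    rows = []
    base_covs = ("site", "age_group", "sex", "year")
    for jur, sub in labelled.groupby("jurisdiction"):
        sub = sub.copy()
        sub["ep"] = sub[definition].astype(bool)
        no_stage = (sub["stage"] == "missing").all()
        stage_data = sub
        if complete_case_stage:
            stage_data = sub[sub["stage"] != "missing"]

        def _fit(data, spec, model_name, horizon=None):
            try:
                ests = fit_logistic(data, spec)
                rows.extend(
                    _estimates_to_rows(ests, jur, model_name, horizon, len(data), definition)
                )
            except (ConvergenceError, AliasedTermError) as e:
                rows.append(
                    {
                        "jurisdiction": jur,
                        "model": model_name,
                        "horizon": horizon,
                        "term": None,
                        "log_or": np.nan,
                        "se": np.nan,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "n": len(data),
                        "definition": definition,
                        "converged": False,
                        "note": str(e),
                    }
                )

        _fit(sub, ModelSpec("ep", base_covs), "ep_risk_1")
        if no_stage:
            rows.append(
                {
                    "jurisdiction": jur, "model": "ep_risk_2", "horizon": None,
                    "term": None, "log_or": np.nan, "se": np.nan, "or": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "n": len(sub),
                    "definition": definition, "converged": False,
                    "note": "no stage data; stage-adjusted model skipped",
                }
            )
        else:
            _fit(stage_data, ModelSpec("ep", base_covs + ("stage",), stage_adjusted=True),
                 "ep_risk_2")

        for h in horizons:
            outcome = f"death_{h}"
            _fit(sub, ModelSpec(outcome, ("ep_status",)), "mortality_crude", h)
            _fit(sub, ModelSpec(outcome, ("ep_status",) + base_covs),
                 "mortality_adj_nostage", h)
            if no_stage:
                rows.append(
                    {
                        "jurisdiction": jur, "model": "mortality_adj_stage",
                        "horizon": h, "term": None, "log_or": np.nan, "se": np.nan,
                        "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "n": len(sub), "definition": definition, "converged": False,
                        "note": "no stage data; stage-adjusted model skipped",
                    }
                )
            else:
                _fit(stage_data,
                     ModelSpec(outcome, ("ep_status",) + base_covs + ("stage",),
                               stage_adjusted=True),
                     "mortality_adj_stage", h)
    return pd.DataFrame(rows)
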