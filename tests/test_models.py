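"""Mortality indicators, 2x2 odds ratios, and the logistic model battery."""

import numpy as np
import pandas as pd
import pytest

import ep_routes as ep
from ep_routes.models import HORIZON_DAYS
from ep_routes.published import mortality_table

from conftest import single_jurisdiction_config


def _rec(death_offset=None, censor_offset=None):
    dx = pd.Timestamp("2015-01-01")
    return {
        "patient_id": "p",
        "diagnosis_date": dx,
        "death_date": dx + pd.Timedelta(days=death_offset) if death_offset is not None else pd.NaT,
        "censor_date": dx + pd.Timedelta(days=censor_offset) if censor_offset is not None else pd.NaT,
    }


@pytest.mark.parametrize(
    "record,expect",
    [
        (_rec(death_offset=300), {"1m": False, "3m": False, "12m": True}),
        (_rec(censor_offset=200), {"1m": False, "3m": False, "12m": False}),
        (_rec(death_offset=40), {"1m": False, "3m": True, "12m": True}),
        (_rec(death_offset=0), {"1m": True, "3m": True, "12m": True}),
        (_rec(death_offset=30), {"1m": True, "3m": True, "12m": True}),
        (_rec(death_offset=31), {"1m": False, "3m": True, "12m": True}),
    ],
)
def test_mortality_indicator_examples(record, expect):
    for h, want in expect.items():
        assert ep.mortality_indicator(record, h) is want


def test_death_before_diagnosis_rejected():
    with pytest.raises(ValueError):
        ep.mortality_indicator(_rec(death_offset=-1), "12m")


def test_mortality_monotone_in_horizon(labelled):
    assert (~labelled["death_1m"] | labelled["death_3m"]).all()
    assert (~labelled["death_3m"] | labelled["death_12m"]).all()
    assert HORIZON_DAYS["1m"] < HORIZON_DAYS["3m"] < HORIZON_DAYS["12m"]


@pytest.mark.parametrize(
    "jurisdiction,printed",
    [("Denmark", 3.88), ("England", 4.85), ("Ontario", 3.66)],
)
def test_crude_or_reproduces_published_values(jurisdiction, printed):
    r = mortality_table().set_index("jurisdiction").loc[jurisdiction]
    est = ep.crude_or(
        r["deaths_ep"], r["n_ep"] - r["deaths_ep"],
        r["deaths_non_ep"], r["n_non_ep"] - r["deaths_non_ep"],
    )
    assert round(est.or_, 2) == printed
    assert est.ci_low < est.or_ < est.ci_high


def test_crude_or_identity_and_zero_cell():
    assert ep.crude_or(7, 7, 7, 7).or_ == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        ep.crude_or(0, 5, 5, 5)


def _expand_2x2(a, b, c, d):
    """Patient-level frame from a 2x2 table (exposed dead/alive, unexposed)."""
    ep_col = [True] * (a + b) + [False] * (c + d)
    dead = [True] * a + [False] * b + [True] * c + [False] * d
    return pd.DataFrame({"ep": ep_col, "death_12m": dead})


def test_saturated_logistic_equals_crude_or():
    """One binary covariate: the logistic OR must equal the 2x2 OR to at
    least 6 significant figures (Denmark's published counts)."""
    r = mortality_table().set_index("jurisdiction").loc["Denmark"]
    a, b = int(r["deaths_ep"]), int(r["n_ep"] - r["deaths_ep"])
    c, d = int(r["deaths_non_ep"]), int(r["n_non_ep"] - r["deaths_non_ep"])
    crude = ep.crude_or(a, b, c, d)
    fit = ep.fit_logistic(_expand_2x2(a, b, c, d), ep.ModelSpec("death_12m", ("ep_status",)))
    (est,) = fit
    assert est.log_or == pytest.approx(crude.log_or, rel=1e-6)
    assert est.se == pytest.approx(crude.se, rel=1e-4)
    assert round(est.or_, 2) == 3.88


def test_null_model_estimates_near_one():
    rng = np.random.default_rng(0)
    n = 5000
    df = pd.DataFrame(
        {
            "ep": rng.random(n) < 0.3,
            "site": rng.choice(["colon", "lung", "pancreas"], n),
            "age_group": rng.choice(["15-64", "85+"], n),
            "death_12m": rng.random(n) < 0.4,  # independent of everything
        }
    )
    ests = ep.fit_logistic(df, ep.ModelSpec("death_12m", ("ep_status", "site", "age_group")))
    for e in ests:
        assert abs(e.log_or) < 3 * e.se


def test_reference_level_change_inverts_or():
    rng = np.random.default_rng(1)
    n = 4000
    df = pd.DataFrame(
        {
            "ep": rng.random(n) < 0.5,
            "death_12m": rng.random(n) < 0.4,
            "site": rng.choice(["colon", "lung"], n),
        }
    )
    a = ep.fit_logistic(df, ep.ModelSpec("death_12m", ("ep_status", "site")))
    b = ep.fit_logistic(
        df, ep.ModelSpec("death_12m", ("ep_status", "site"), {"site": "lung"})
    )
    site_a = next(e for e in a if e.term.startswith("site="))
    site_b = next(e for e in b if e.term.startswith("site="))
    assert site_a.log_or == pytest.approx(-site_b.log_or, abs=1e-8)


def test_separation_raises_convergence_error():
    df = pd.DataFrame({"ep": [True] * 20 + [False] * 20,
                       "death_12m": [True] * 20 + [False] * 20})
    with pytest.raises(ep.models.ConvergenceError):
        ep.fit_logistic(df, ep.ModelSpec("death_12m", ("ep_status",)))


def test_jurisdiction_battery_completeness(labelled):
    out = ep.run_jurisdiction_models(labelled, horizons=("12m",))
    for jur in labelled["jurisdiction"].unique():
        sub = out[(out["jurisdiction"] == jur) & (out["model"] == "mortality_adj_stage")]
        assert (sub["term"] == "ep_status=True").any()
    assert set(out["model"]) == {
        "ep_risk_1", "ep_risk_2",
        "mortality_crude", "mortality_adj_nostage", "mortality_adj_stage",
    }


def test_stageless_jurisdiction_flagged_not_fatal():
    cfg = single_jurisdiction_config(seed=21, n=2000)
    cfg.jurisdictions[0].stage_available = False
    tum, adm = ep.generate_cohort(cfg)
    tum, _ = ep.apply_inclusion_criteria(tum)
    labels = ep.classify_cohort(tum, adm)
    labelled = ep.add_mortality_indicators(
        tum.merge(labels.drop(columns=["anchor_admission_date"]), on="patient_id")
    )
    out = ep.run_jurisdiction_models(labelled, horizons=("12m",))
    skipped = out[out["model"] == "mortality_adj_stage"]
    assert (~skipped["converged"].astype(bool)).all()
    assert skipped["note"].str.contains("no stage data").all()
    # the rest of the battery still ran
    assert out[out["model"] == "mortality_crude"]["converged"].astype(bool).any()


def test_adjusted_close_to_crude_without_confounding():
    """Covariates independent of EP: adjustment must not move the EP log-OR
    by more than Monte-Carlo jitter at large n."""
    cfg = single_jurisdiction_config(seed=22, n=100_000)
    # remove all covariate effects: EP and mortality depend on nothing but
    # each other, so the odds ratio is collapsible and crude == adjusted
    # up to Monte-Carlo error
    for model in (cfg.ep_model, cfg.mortality_model):
        model.site = {}
        model.age_group = {}
        model.sex = {}
        model.stage = {}
    cfg.ep_model.intercept = -0.85
    cfg.mortality_model.intercept = -0.6
    tum, _ = ep.generate_cohort(cfg)
    tum, _ = ep.apply_inclusion_criteria(tum)
    tum["ep"] = tum["latent_ep"]
    tum = ep.add_mortality_indicators(tum)
    crude = ep.fit_logistic(tum, ep.ModelSpec("death_12m", ("ep_status",)))[0]
    adj = next(
        e
        for e in ep.fit_logistic(
            tum, ep.ModelSpec("death_12m", ("ep_status", "site", "age_group", "sex", "stage"))
        )
        if e.term == "ep_status=True"
    )
    assert adj.or_ == pytest.approx(3.0, rel=0.06)
    assert abs(crude.log_or - adj.log_or) < 0.03
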