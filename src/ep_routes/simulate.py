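"""Synthetic linked registry + admissions data generator.

Produces, per configured jurisdiction, a tumour table and an admissions
table with the statistical structure the downstream analysis assumes:

* covariates (site, age group, sex, latent 4-level stage) drawn
  independently from configured mixes;
* a latent emergency-presentation (EP) indicator drawn from a logistic
  model on those covariates;
* an admission history consistent with the EP status — broad-EP cases
  get one emergency admission 0-30 days before diagnosis and, with
  probability ``narrow_discordance``, an elective admission strictly
  between the emergency admission and diagnosis (so the case is broad-
  but not narrow-EP); non-EP cases get no emergency admission in the
  window (optionally an elective inside it, or an emergency strictly
  before it);
* a 12-month death indicator drawn from a logistic model including the
  EP effect, with the death date uniform in (diagnosis, diagnosis+365]
  and survivors censored at diagnosis+400 days.

Everything is deterministic given ``config.seed``.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    AGE_GROUPS,
    SEXES,
    SITES,
    STAGE_LEVELS,
    STAGE_MISSING,
    SimulationConfig,
)

# Representative ICD-10 topography codes per site (sampled uniformly).
SITE_ICD10 = {
    "oesophagus": ["C15"],
    "stomach": ["C16"],
    "colon": ["C18", "C19"],
    "rectum": ["C20"],
    "liver": ["C22"],
    "pancreas": ["C25", "C25.9"],
    "lung": ["C34"],
    "ovary": ["C56", "C48.1", "C48.2", "C57.0"],
}

# Observed stage for registries using a 3-level classification: the two
# intermediate latent levels collapse into one regional category.
_COLLAPSE_3LEVEL = {"1": "1", "2": "2", "3": "2", "4": "3"}

_CENSOR_OFFSET_DAYS = 400


def _draw_levels(rng, levels, mix, n):
    p = np.array([mix[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=p)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate linked (tumour, admission) tables for every jurisdiction.

    Returns
    -------
    tumours, admissions : DataFrame
        Tumours: one row per patient with diagnosis, demographics, observed
        stage, latent generating fields (``latent_ep``, ``latent_stage``)
        and follow-up dates.  Admissions: zero or more rows per patient
        with ``admission_date`` and ``admission_type``.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.diagnosis_period
    period_start = np.datetime64(f"{y0}-01-01")
    period_days = int(
        (np.datetime64(f"{y1}-12-31") - period_start) / np.timedelta64(1, "D")
    ) + 1
    window = config.window_days

    tum_frames, adm_frames = [], []
    for jur in config.jurisdictions:
        n = jur.n_patients
        pid = np.array([f"{jur.name}-{i:07d}" for i in range(n)], dtype=object)
        site = _draw_levels(rng, SITES, config.site_mix, n)
        age = _draw_levels(rng, AGE_GROUPS, config.age_mix, n)
        sex = _draw_levels(rng, SEXES, config.sex_mix, n)
        latent_stage = _draw_levels(rng, STAGE_LEVELS, config.stage_mix, n)

        dx = period_start + rng.integers(0, period_days, size=n).astype("timedelta64[D]")

        p_ep = expit(
            config.ep_model.log_odds(site, age, sex, latent_stage)
            + jur.ep_intercept_shift
        )
        ep = rng.random(n) < p_ep
        discordant = ep & (rng.random(n) < config.narrow_discordance)

        # Emergency admission offset before diagnosis: uniform 0-window days;
        # discordant cases need >= 2 days so a strictly-between elective exists.
        em_offset = rng.integers(0, window + 1, size=n)
        em_offset = np.where(discordant, rng.integers(2, window + 1, size=n), em_offset)

        # Elective strictly between emergency admission and diagnosis.
        elect_offset = np.array(
            [rng.integers(1, o) if d else 0 for o, d in zip(em_offset, discordant)]
        )

        non_ep = ~ep
        noise_elect = non_ep & (rng.random(n) < config.elective_noise_frac)
        noise_elect_offset = rng.integers(0, window + 1, size=n)
        pre_window_em = non_ep & (rng.random(n) < config.out_of_window_emergency_frac)
        pre_window_offset = rng.integers(window + 1, 121, size=n)

        lo = config.mortality_model.log_odds(site, age, sex, latent_stage)
        p_death = expit(lo + np.where(ep, config.mortality_model.ep_log_or, 0.0))
        dead = rng.random(n) < p_death
        death_offset = rng.integers(1, 366, size=n)
        death_date = np.where(
            dead, dx + death_offset.astype("timedelta64[D]"), np.datetime64("NaT")
        )
        censor_date = np.where(
            dead, np.datetime64("NaT"), dx + np.timedelta64(_CENSOR_OFFSET_DAYS, "D")
        )

        # Observed stage: registry artifact of the latent truth.
        if not jur.stage_available:
            stage = np.full(n, STAGE_MISSING, dtype=object)
        else:
            if jur.stage_levels == 3:
                stage = np.array([_COLLAPSE_3LEVEL[s] for s in latent_stage], dtype=object)
            else:
                stage = latent_stage.copy()
            miss = rng.random(n) < jur.stage_missing_frac
            stage[miss] = STAGE_MISSING

        icd10 = np.array(
            [SITE_ICD10[s][rng.integers(len(SITE_ICD10[s]))] for s in site], dtype=object
        )

        tum_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "jurisdiction": jur.name,
                    "icd10": icd10,
                    "histology": 8140,
                    "behaviour": 3,
                    "diagnosis_date": pd.to_datetime(dx),
                    "age_group": age,
                    "sex": sex,
                    "stage": stage,
                    "year": pd.to_datetime(dx).year,
                    "death_date": pd.to_datetime(death_date),
                    "censor_date": pd.to_datetime(censor_date),
                    "latent_ep": ep,
                    "latent_stage": latent_stage,
                }
            )
        )

        rows = []
        em_dates = dx - em_offset.astype("timedelta64[D]")
        el_dates = dx - elect_offset.astype("timedelta64[D]")
        ne_dates = dx - noise_elect_offset.astype("timedelta64[D]")
        pw_dates = dx - pre_window_offset.astype("timedelta64[D]")
        for i in range(n):
            if ep[i]:
                rows.append((pid[i], em_dates[i], "emergency"))
                if discordant[i]:
                    rows.append((pid[i], el_dates[i], "elective"))
            else:
                if noise_elect[i]:
                    rows.append((pid[i], ne_dates[i], "elective"))
                if pre_window_em[i]:
                    rows.append((pid[i], pw_dates[i], "emergency"))
        adm_frames.append(
            pd.DataFrame(rows, columns=["patient_id", "admission_date", "admission_type"])
        )

    tumours = pd.concat(tum_frames, ignore_index=True)
    admissions = pd.concat(adm_frames, ignore_index=True)
    admissions["admission_date"] = pd.to_datetime(admissions["admission_date"])
    return tumours, admissions


def implied_ep_marginal(config: SimulationConfig) -> float:
    """Exact EP marginal probability implied by the mixes and ep_model.

    Enumerates the 8x4x2x4 covariate grid (covariates are independent by
    construction), averages the logistic probabilities per jurisdiction
    (which may shift the intercept), and weights jurisdictions by size.
    """
    n_total = sum(j.n_patients for j in config.jurisdictions)
    total = 0.0
    for jur in config.jurisdictions:
        for s, a, x, g in itertools.product(SITES, AGE_GROUPS, SEXES, STAGE_LEVELS):
            w = (
                config.site_mix[s]
                * config.age_mix[a]
                * config.sex_mix[x]
                * config.stage_mix[g]
            )
            lo = config.ep_model.log_odds(
                np.array([s]), np.array([a]), np.array([x]), np.array([g])
            )[0]
            total += (jur.n_patients / n_total) * w * expit(lo + jur.ep_intercept_shift)
    return total


def write_cohort(tumours: pd.DataFrame, admissions: pd.DataFrame, outdir) -> None:
    """Write tumours.csv / admissions.csv with ISO-8601 dates.

    The latent generating columns are dropped: they exist only inside the
    simulator, never in the exchanged data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tum = tumours.drop(columns=[c for c in tumours.columns if c.startswith("latent_")])
    for col in ("diagnosis_date", "death_date", "censor_date"):
        tum[col] = tum[col].dt.strftime("%Y-%m-%d")
    adm = admissions.copy()
    adm["admission_date"] = adm["admission_date"].dt.strftime("%Y-%m-%d")
    tum.to_csv(outdir / "tumours.csv", index=False)
    adm.to_csv(outdir / "admissions.csv", index=False)


def read_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    tumours = pd.read_csv(indir / "tumours.csv", dtype={"patient_id": str, "stage": str})
    for col in ("diagnosis_date", "death_date", "censor_date"):
        tumours[col] = pd.to_datetime(tumours[col])
    admissions = pd.read_csv(indir / "admissions.csv", dtype={"patient_id": str})
    admissions["admission_date"] = pd.to_datetime(admissions["admission_date"])
    return tumours, admissions


def generate_net_survival_table(
    config: SimulationConfig,
    ep_slope: float = -5.0,
    noise_sd: float = 2.0,
    baseline: float = 75.0,
    definition_offset: float = 0.0,
    cohort: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Jurisdiction-level table for the ecological stage.

    EP percentages are measured from the simulated cohort under each
    jurisdiction's own definition; 1-year net survival is then a linear
    function of EP% (``ep_slope`` per 10 percentage points) plus an
    optional narrow-definition offset and Gaussian noise.
    """
    from .classify import classify_cohort

    if not np.isfinite(ep_slope):
        raise ValueError("ep_slope must be finite")
    if cohort is None:
        cohort = generate_cohort(config)
    tumours, admissions = cohort
    labels = classify_cohort(tumours, admissions, window_days=config.window_days)
    merged = tumours[["patient_id", "jurisdiction"]].merge(labels, on="patient_id")

    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for jur in config.jurisdictions:
        sub = merged[merged["jurisdiction"] == jur.name]
        col = "broad" if jur.definition_type == "broad" else "narrow"
        ep_pct = 100.0 * sub[col].mean()
        narrow_ind = 1.0 if jur.definition_type == "narrow" else 0.0
        ns = (
            baseline
            + (ep_slope / 10.0) * ep_pct
            + definition_offset * narrow_ind
            + rng.normal(0.0, noise_sd)
        )
        rows.append((jur.name, jur.definition_type, ep_pct, ns))
    return pd.DataFrame(
        rows, columns=["jurisdiction", "definition_type", "ep_pct", "net_survival_1yr"]
    )
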