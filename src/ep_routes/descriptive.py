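"""Stratified EP percentages, Wilson score intervals, and site-ordering
concordance across jurisdictions."""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import SITES


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, on the 0-1 scale.

    Centre (p + z²/2n)/(1 + z²/n), half-width z·sqrt(p(1-p)/n + z²/4n²)
    /(1 + z²/n); no continuity correction.  Bounds are guaranteed inside
    [0, 1], unlike the Wald interval.
    """
    if n < 1:
        raise ValueError("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # clamp floating-point fuzz at the boundaries (k=0 / k=n)
    low = 0.0 if k == 0 else max(0.0, float(low))
    high = 1.0 if k == n else min(1.0, float(high))
    return low, high


def ep_percentage_by_stratum(
    labelled: pd.DataFrame,
    stratify_by: list[str],
    definition: str = "broad",
    conf: float = 0.95,
) -> pd.DataFrame:
    """EP percentage with Wilson CI per stratum combination.

    ``labelled`` is the tumour table joined to EP labels; ``definition``
    names the boolean label column to summarise.  Output percentages are
    on the 0-100 scale at full precision (round only for presentation).
    """
    unknown = [v for v in stratify_by if v not in labelled.columns]
    if unknown:
        raise KeyError(f"unknown stratification variable(s): {unknown}")
    if definition not in labelled.columns:
        raise KeyError(f"no label column {definition!r}")

    grouped = labelled.groupby(stratify_by, observed=True, dropna=False)[definition]
    out = grouped.agg(n="size", k="sum").reset_index()
    out["k"] = out["k"].astype(int)
    out["pct"] = 100.0 * out["k"] / out["n"]
    ci = [wilson_interval(k, n, conf) for k, n in zip(out["k"], out["n"])]
    out["ci_low"] = [100.0 * lo for lo, _ in ci]
    out["ci_high"] = [100.0 * hi for _, hi in ci]
    out["definition"] = definition
    return out


def site_order_concordance(
    site_pct: pd.DataFrame,
    reference: str,
    method: str = "pearson",
) -> dict[str, float]:
    """Pairwise correlation of site-level EP percentages vs a reference.

    ``site_pct`` is a jurisdiction x site matrix of EP percentages (all
    eight sites present).  Returns reference-vs-other correlations; high
    values mean the ordering of cancer sites by EP percentage is
    concordant across jurisdictions.  ``method`` is ``"pearson"`` (on
    the percentages) or ``"spearman"`` (on ranks).
    """
    missing = [s for s in SITES if s not in site_pct.columns]
    if missing:
        raise KeyError(f"site columns missing: {missing}")
    if reference not in site_pct.index:
        raise KeyError(f"reference jurisdiction {reference!r} not in table")
    mat = site_pct[list(SITES)].astype(float)
    if (mat.std(axis=1) == 0).any():
        raise ValueError("zero variance in a site-percentage vector")
    ref = mat.loc[reference].to_numpy()
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    return {
        jur: float(corr(ref, mat.loc[jur].to_numpy())[0])
        for jur in mat.index
        if jur != reference
    }
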