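"""Jurisdiction-level (ecological) association between EP percentage and
1-year net survival.

For one cancer site, ordinary least squares of jurisdiction-level net
survival on jurisdiction-level EP percentage plus a narrow-definition
indicator (dropped automatically when only one definition type is
present).  The slope is reported per 10 percentage points of EP.  Net
survival is an external input (published estimates), never computed
here; the regression is unweighted, treating every jurisdiction point
alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class SingularDesignError(ValueError):
    """EP percentage is constant across points; slope not identifiable."""


@dataclass(frozen=True)
class JurisdictionPoint:
    jurisdiction: str
    site: str
    ep_pct: float
    net_survival_1yr: float
    definition_type: str = "broad"

    def __post_init__(self):
        if not 0 <= self.ep_pct <= 100:
            raise ValueError("ep_pct must be in [0, 100]")
        if not 0 <= self.net_survival_1yr <= 100:
            raise ValueError("net_survival_1yr must be in [0, 100]")


@dataclass
class EcologicalFit:
    site: str
    beta_per_10pct: float
    ci_low: float
    ci_high: float
    p_value: float
    definition_offset: float | None
    r2: float
    k: int


def _as_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        return points.copy()
    return pd.DataFrame([p.__dict__ for p in points])


def fit_ecological(points, site: str | None = None) -> EcologicalFit:
    """OLS of net survival on EP% (+ narrow indicator), one cancer site.

    ``points`` is a list of :class:`JurisdictionPoint` or a DataFrame with
    columns ``ep_pct, net_survival_1yr, definition_type`` (and optionally
    ``site``).  The reported ``beta_per_10pct`` is 10x the per-1% slope;
    its CI and two-sided p-value come from the t distribution with the
    model's residual degrees of freedom; ``r2`` is the full-model R^2.
    """
    df = _as_frame(points)
    if site is None:
        site = str(df["site"].iloc[0]) if "site" in df.columns else ""
    x = df["ep_pct"].to_numpy(dtype=float)
    y = df["net_survival_1yr"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise SingularDesignError("ep_pct constant across jurisdictions")

    narrow = (df["definition_type"] == "narrow").to_numpy(dtype=float)
    use_offset = 0 < narrow.sum() < len(narrow)
    cols = {"ep_pct": x}
    if use_offset:
        cols["narrow"] = narrow
    X = sm.add_constant(pd.DataFrame(cols))
    if len(df) < X.shape[1] + 1:
        raise ValueError(
            f"need at least {X.shape[1] + 1} points for {X.shape[1]} parameters"
        )
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    slope = float(res.params["ep_pct"])
    if np.allclose(res.resid, 0):
        # Exact fit: zero residual variance makes the t-based CI degenerate.
        lo = hi = slope
        p = 0.0 if slope != 0 else 1.0
    else:
        lo, hi = float(ci.loc["ep_pct", 0]), float(ci.loc["ep_pct", 1])
        p = float(res.pvalues["ep_pct"])
    return EcologicalFit(
        site=site,
        beta_per_10pct=10.0 * slope,
        ci_low=10.0 * lo,
        ci_high=10.0 * hi,
        p_value=p,
        definition_offset=float(res.params["narrow"]) if use_offset else None,
        r2=float(res.rsquared) if np.ptp(y) > 0 else 0.0,
        k=len(df),
    )


def simulate_ecological_points(
    n_jurisdictions: int,
    slope_per_10pct: float,
    noise_sd: float,
    rng: np.random.Generator,
    site: str = "colon",
    baseline: float = 75.0,
    definition_offset: float = 2.0,
    narrow_fraction: float = 5 / 17,
) -> pd.DataFrame:
    """Lightweight jurisdiction-point generator for replicate studies.

    EP percentages are uniform on 15-50%, a fixed fraction of
    jurisdictions use the narrow definition, and net survival is linear
    in EP% with Gaussian noise — the generating model the ecological fit
    assumes, so recovery and CI coverage can be checked directly.
    """
    ep = rng.uniform(15, 50, n_jurisdictions)
    n_narrow = round(narrow_fraction * n_jurisdictions)
    narrow = np.zeros(n_jurisdictions, dtype=bool)
    narrow[:n_narrow] = True
    ns = (
        baseline
        + slope_per_10pct / 10.0 * ep
        + definition_offset * narrow
        + rng.normal(0, noise_sd, n_jurisdictions)
    )
    ns = np.clip(ns, 0, 100)
    return pd.DataFrame(
        {
            "jurisdiction": [f"J{i:02d}" for i in range(n_jurisdictions)],
            "site": site,
            "ep_pct": ep,
            "net_survival_1yr": ns,
            "definition_type": np.where(narrow, "narrow", "broad"),
        }
    )
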