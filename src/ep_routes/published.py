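"""Published jurisdiction-level aggregate inputs.

Under the federated contract the central stages operate on published
aggregates, never patient-level data.  This module carries the
jurisdiction-level aggregates reported by the International Cancer
Benchmarking Partnership (ICBP) emergency-presentation analysis of 14
jurisdictions in six countries (2012-17 diagnoses, eight cancer sites):

* the jurisdiction x site EP percentage matrix, with each
  jurisdiction's operational definition (broad or narrow);
* per-jurisdiction 12-month mortality counts by EP status with crude,
  adjusted (no stage) and stage-adjusted odds ratios (printed OR and
  95% CI);
* headline numerator/denominator pairs for the overall EP range and
  the site extremes.

These are inputs to the central collation, concordance, and
meta-analysis stages, exactly as a central coordinating team would
receive them.
"""

from __future__ import annotations

import pandas as pd

from .meta import StudyEstimate, se_from_ci

#: Jurisdictions using the narrow operational definition.
NARROW_JURISDICTIONS = frozenset(
    {"Denmark", "England", "Northern Ireland", "New South Wales", "Victoria"}
)

_SITE_COLUMNS = (
    "oesophagus", "stomach", "colon", "rectum", "liver", "pancreas", "lung", "ovary",
)

# jurisdiction: (all-sites %, then the eight site percentages in _SITE_COLUMNS order)
_EP_PCT = {
    "Denmark": (30.9, 24.3, 32.2, 28.3, 13.5, 43.3, 48.0, 36.4, 20.6),
    "England": (31.3, 19.7, 31.4, 29.3, 10.7, 42.4, 46.9, 34.7, 34.8),
    "Northern Ireland": (27.9, 19.9, 29.6, 23.8, 9.1, 36.9, 42.7, 32.0, 29.6),
    "New South Wales": (30.9, 26.9, 30.5, 27.6, 12.1, 36.8, 45.3, 36.4, 28.4),
    "Victoria": (24.0, 20.0, 23.7, 22.9, 9.1, 31.9, 34.1, 27.8, 20.9),
    "Norway": (36.5, 32.7, 40.0, 35.8, 15.8, 50.6, 55.4, 39.4, 34.9),
    "Scotland": (38.5, 25.2, 39.1, 35.1, 14.1, 47.5, 59.2, 42.1, 42.8),
    "Wales": (37.4, 25.5, 39.1, 34.2, 13.8, 50.5, 56.7, 41.5, 40.8),
    "Alberta": (30.0, 23.0, 34.6, 28.6, 12.9, 31.7, 40.9, 33.3, 25.7),
    "Atlantic Canada": (26.9, 20.7, 30.4, 28.4, 12.6, 34.3, 38.8, 26.6, 28.1),
    "British Columbia": (30.5, 28.3, 40.3, 27.5, 12.0, 38.1, 41.4, 33.2, 31.7),
    "Ontario": (26.1, 20.3, 26.9, 27.2, 11.0, 28.3, 35.3, 27.5, 23.9),
    "Saskatchewan-Manitoba": (28.3, 18.5, 31.8, 27.7, 13.7, 33.3, 37.3, 30.6, 30.1),
    "New Zealand": (42.5, 36.8, 47.8, 36.6, 19.8, 49.7, 60.4, 51.1, 48.1),
}


def ep_percentage_matrix() -> pd.DataFrame:
    """Jurisdiction x site EP percentages (the all-sites column dropped)."""
    rows = {j: v[1:] for j, v in _EP_PCT.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(_SITE_COLUMNS))
    df.index.name = "jurisdiction"
    return df


# Per jurisdiction: non-EP (n, deaths), EP (n, deaths), then printed
# crude / adjusted-no-stage / stage-adjusted OR (value, lo, hi), and whether
# the registry contributed stage data across all eight sites.
_MORTALITY = {
    "Denmark": ((31804, 9013), (14199, 8597),
                (3.88, 3.72, 4.05), (3.28, 3.13, 3.43), (2.62, 2.49, 2.76), True),
    "Norway": ((29281, 7222), (16866, 10107),
               (4.57, 4.39, 4.76), (4.37, 4.17, 4.58), (3.31, 3.15, 3.49), True),
    "England": ((256260, 99437), (116934, 88261),
                (4.85, 4.78, 4.93), (4.54, 4.46, 4.62), (3.46, 3.39, 3.53), True),
    "Northern Ireland": ((11179, 4328), (4322, 3380),
                         (5.68, 5.24, 6.17), (5.46, 4.98, 5.99), (3.53, 3.19, 3.92), True),
    "Scotland": ((27708, 10910), (17321, 12507),
                 (4.00, 3.84, 4.17), (3.60, 3.44, 3.77), (2.95, 2.80, 3.11), True),
    "Wales": ((16376, 6253), (9763, 7017),
              (4.14, 3.92, 4.37), (3.79, 3.57, 4.03), (2.99, 2.79, 3.19), True),
    "Alberta": ((17741, 5599), (7441, 4839),
                (4.03, 3.81, 4.27), (3.86, 3.62, 4.12), (2.63, 2.45, 2.83), True),
    "Atlantic Canada": ((8065, 2745), (2905, 1855),
                        (3.42, 3.13, 3.74), (3.79, 3.42, 4.21), (2.74, 2.44, 3.08), True),
    "British Columbia": ((11295, 3555), (5195, 3320),
                         (3.84, 3.59, 4.12), (4.01, 3.70, 4.36), (3.11, 2.85, 3.39), False),
    "Ontario": ((68316, 20197), (24131, 14623),
                (3.66, 3.55, 3.78), (3.87, 3.74, 4.00), (2.95, 2.84, 3.06), True),
    "Saskatchewan-Manitoba": ((5985, 1955), (2400, 1520),
                              (3.57, 3.24, 3.95), (3.77, 3.36, 4.24), (2.72, 2.39, 3.09), True),
    "New South Wales": ((36753, 9663), (16445, 9836),
                        (4.17, 4.01, 4.34), (3.74, 3.58, 3.91), (2.89, 2.75, 3.03), True),
    "Victoria": ((29047, 7557), (9165, 5328),
                 (3.95, 3.76, 4.15), (3.70, 3.50, 3.92), (3.33, 3.15, 3.53), False),
    "New Zealand": ((16556, 4653), (12238, 7572),
                    (4.15, 3.95, 4.36), (3.73, 3.53, 3.95), (2.57, 2.42, 2.74), True),
}


def mortality_table() -> pd.DataFrame:
    """12-month mortality counts and printed ORs, one row per jurisdiction."""
    rows = []
    for jur, ((n0, d0), (n1, d1), crude, adj, stage, full_stage) in _MORTALITY.items():
        rows.append(
            {
                "jurisdiction": jur,
                "definition_type": "narrow" if jur in NARROW_JURISDICTIONS else "broad",
                "n_non_ep": n0, "deaths_non_ep": d0,
                "n_ep": n1, "deaths_ep": d1,
                "crude_or": crude[0], "crude_lo": crude[1], "crude_hi": crude[2],
                "adj_or": adj[0], "adj_lo": adj[1], "adj_hi": adj[2],
                "stage_or": stage[0], "stage_lo": stage[1], "stage_hi": stage[2],
                "stage_all_sites": full_stage,
            }
        )
    return pd.DataFrame(rows)


def stage_adjusted_study_estimates() -> list[StudyEstimate]:
    """Meta-analysis inputs: the 12 stage-adjusted 12-month-mortality ORs.

    Jurisdictions without stage data across all eight sites (British
    Columbia, Victoria) are excluded; SEs are back-derived from the
    printed 95% CIs.
    """
    import math

    out = []
    for _, r in mortality_table().iterrows():
        if not r["stage_all_sites"]:
            continue
        out.append(
            StudyEstimate(
                jurisdiction=r["jurisdiction"],
                log_or=math.log(r["stage_or"]),
                se=se_from_ci(r["stage_or"], r["stage_lo"], r["stage_hi"]),
                definition_type=r["definition_type"],
            )
        )
    return out


# Headline numerator/denominator pairs (k, n).
EP_RANGE_LOW = (9165, 38212)        # lowest all-sites EP% jurisdiction
EP_RANGE_HIGH = (12238, 28794)      # highest all-sites EP% jurisdiction
PANCREAS_POOLED = (30972, 67173)    # highest-EP site, pooled
RECTUM_POOLED = (10051, 83325)      # lowest-EP site, pooled
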