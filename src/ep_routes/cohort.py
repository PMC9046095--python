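"""Cohort eligibility rules and ICD-10 site mapping.

The analysed population: patients aged 15-99 with a new primary invasive
(behaviour code 3) diagnosis of one of eight cancers — oesophageal (C15),
stomach (C16), colon (C18-19), rectal (C20), liver (C22), pancreatic
(C25), lung (C34) or ovarian (C48.1-2, C56, C57.0, the latter including
peritoneal and fallopian-tube cancers) — diagnosed in the study period,
with borderline ovarian morphologies (ICD-O-3 8442, 8451, 8462, 8472,
8473) excluded.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .config import AGE_GROUPS

#: ICD-O-3 morphology codes for borderline ovarian tumours (excluded).
BORDERLINE_OVARIAN_MORPHOLOGY = frozenset({8442, 8451, 8462, 8472, 8473})

# Sites resolvable at 3-character precision.
_PREFIX_SITES = {
    "C15": "oesophagus",
    "C16": "stomach",
    "C18": "colon",
    "C19": "colon",
    "C20": "rectum",
    "C22": "liver",
    "C25": "pancreas",
    "C34": "lung",
    "C56": "ovary",
}
# Sites requiring 4-character precision (only these sub-codes qualify).
_FOURCHAR_SITES = {"C481": "ovary", "C482": "ovary", "C570": "ovary"}

_CODE_RE = re.compile(r"^[A-Z]\d{2}(\.?\d)?$")

DEFAULT_STUDY_PERIOD = (2012, 2017)


class InvalidICD10Error(ValueError):
    """Raised for a syntactically malformed ICD-10 topography code."""


def classify_cancer_site(icd10: str) -> str | None:
    """Map an ICD-10 topography code to one of the eight analysed sites.

    Accepts dotted ("C48.1") and undotted ("C481") forms, at 3- or
    4-character precision.  Codes outside the analysed ranges return
    ``None``; malformed codes raise :class:`InvalidICD10Error`.

    >>> classify_cancer_site("C18")
    'colon'
    >>> classify_cancer_site("C48.3") is None
    True
    """
    if not isinstance(icd10, str):
        raise InvalidICD10Error(f"not a string: {icd10!r}")
    code = icd10.strip().upper()
    if not _CODE_RE.match(code):
        raise InvalidICD10Error(f"malformed ICD-10 code: {icd10!r}")
    code = code.replace(".", "")
    if code in _FOURCHAR_SITES:
        return _FOURCHAR_SITES[code]
    return _PREFIX_SITES.get(code[:3])


@dataclass
class EligibilityReport:
    """Tally of inclusion/exclusion decisions over an input tumour table."""

    n_input: int
    n_excluded: int
    n_included: int
    exclusion_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_input == self.n_excluded + self.n_included
        assert sum(self.exclusion_reasons.values()) == self.n_excluded

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# Precedence of exclusion reasons: a record failing several rules is counted
# once, under the first failing reason in this order.
EXCLUSION_PRECEDENCE = (
    "missing_diagnosis_date",
    "unmappable_site",
    "age_out_of_range",
    "non_invasive_behaviour",
    "borderline_ovarian_morphology",
    "year_outside_study_period",
)


def _band_age(age: float) -> str | None:
    if age < 15 or age > 99:
        return None
    if age <= 64:
        return "15-64"
    if age <= 74:
        return "65-74"
    if age <= 84:
        return "75-84"
    return "85+"


def apply_inclusion_criteria(
    tumours: pd.DataFrame,
    study_period: tuple[int, int] = DEFAULT_STUDY_PERIOD,
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Filter a raw tumour table to the analysed cohort.

    Adds a ``site`` column for included records.  A raw ``age`` column,
    when present, is banded into the grouped ``age_group`` first (ages
    outside 15-99 are ineligible); otherwise eligibility is evaluated on
    ``age_group`` directly, whose four bands already span 15-99.
    """
    df = tumours.copy()
    n_input = len(df)

    if "age" in df.columns:
        banded = df["age"].map(_band_age)
        df["age_group"] = banded.where(banded.notna(), other=None)

    site = df["icd10"].map(
        lambda c: classify_cancer_site(c) if isinstance(c, str) and _CODE_RE.match(c.strip().upper()) else None
    )
    df["site"] = site

    fails = pd.DataFrame(index=df.index)
    fails["missing_diagnosis_date"] = df["diagnosis_date"].isna()
    fails["unmappable_site"] = site.isna()
    fails["age_out_of_range"] = ~df["age_group"].isin(AGE_GROUPS)
    fails["non_invasive_behaviour"] = df["behaviour"] != 3
    fails["borderline_ovarian_morphology"] = (site == "ovary") & df["histology"].isin(
        BORDERLINE_OVARIAN_MORPHOLOGY
    )
    y0, y1 = study_period
    fails["year_outside_study_period"] = ~df["year"].between(y0, y1)

    excluded_any = fails.any(axis=1)
    reasons: dict[str, int] = {}
    remaining = excluded_any.copy()
    for reason in EXCLUSION_PRECEDENCE:
        hit = remaining & fails[reason]
        k = int(hit.sum())
        if k:
            reasons[reason] = k
        remaining &= ~hit

    included = df.loc[~excluded_any].copy()
    report = EligibilityReport(
        n_input=n_input,
        n_excluded=int(excluded_any.sum()),
        n_included=len(included),
        exclusion_reasons=reasons,
    )
    return included, report
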