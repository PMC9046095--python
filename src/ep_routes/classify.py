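"""Emergency-presentation classification from linked admission histories.

A diagnosis is an emergency presentation (broad definition) when it
occurs within ``window_days`` (default 30) after an emergency hospital
inpatient admission, both boundary days inclusive: an admission on the
diagnosis day itself qualifies, as does one exactly ``window_days``
before.  The narrow definition additionally requires some qualifying
emergency admission with no elective admission strictly between it and
the diagnosis.  Both definitions are contextual: they use only dates
and the emergency/elective admission type, never admission diagnosis
codes.  All arithmetic is on calendar days; same-day events cannot be
ordered, so a same-day elective is never "intervening".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

import pandas as pd

DEFAULT_WINDOW_DAYS = 30


@dataclass(frozen=True)
class Admission:
    """One inpatient admission (emergency or elective)."""

    admission_date: date
    admission_type: str  # "emergency" | "elective"


@dataclass(frozen=True)
class EPLabel:
    patient_id: str
    broad: bool
    narrow: bool
    anchor_admission_date: date | None
    window_days: int

    def __post_init__(self):
        assert not (self.narrow and not self.broad), "narrow implies broad"
        assert (self.anchor_admission_date is not None) == self.broad


def _days(a: date, b: date) -> int:
    return (a - b).days


def classify_broad(
    diagnosis_date: date,
    admissions: list[Admission],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> tuple[bool, date | None]:
    """Broad EP status and the anchor (latest qualifying emergency) date."""
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    qualifying = [
        a.admission_date
        for a in admissions
        if a.admission_type == "emergency"
        and 0 <= _days(diagnosis_date, a.admission_date) <= window_days
    ]
    if not qualifying:
        return False, None
    return True, max(qualifying)


def classify_narrow(
    diagnosis_date: date,
    admissions: list[Admission],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> bool:
    """Narrow EP: some qualifying emergency has no intervening elective.

    An elective intervenes when its date is strictly after the emergency
    admission and strictly before the diagnosis.  It suffices to examine
    the latest qualifying emergency: any elective intervening for it
    intervenes for every earlier qualifying emergency too.
    """
    broad, anchor = classify_broad(diagnosis_date, admissions, window_days)
    if not broad:
        return False
    return not any(
        a.admission_type == "elective"
        and anchor < a.admission_date < diagnosis_date
        for a in admissions
    )


def classify_cohort(
    tumours: pd.DataFrame,
    admissions: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Vectorised per-patient classification of a whole cohort.

    Returns one row per tumour record: ``patient_id, broad, narrow,
    anchor_admission_date, window_days``.  Admissions referencing an
    unknown patient are ignored with a warning.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    known = set(tumours["patient_id"])
    orphan = ~admissions["patient_id"].isin(known)
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} admission(s) reference unknown patients; ignored",
            stacklevel=2,
        )
        admissions = admissions.loc[~orphan]

    merged = admissions.merge(
        tumours[["patient_id", "diagnosis_date"]], on="patient_id", how="left"
    )
    offset = (merged["diagnosis_date"] - merged["admission_date"]).dt.days
    is_em = merged["admission_type"] == "emergency"
    qualifying = is_em & (offset >= 0) & (offset <= window_days)

    anchor = (
        merged.loc[qualifying]
        .groupby("patient_id")["admission_date"]
        .max()
        .rename("anchor_admission_date")
    )

    labels = tumours[["patient_id", "diagnosis_date"]].merge(
        anchor, on="patient_id", how="left"
    )
    labels["broad"] = labels["anchor_admission_date"].notna()

    # Intervening electives relative to the latest qualifying emergency.
    elect = merged.loc[merged["admission_type"] == "elective",
                       ["patient_id", "admission_date", "diagnosis_date"]]
    elect = elect.merge(anchor, on="patient_id", how="inner")
    intervening = elect.loc[
        (elect["admission_date"] > elect["anchor_admission_date"])
        & (elect["admission_date"] < elect["diagnosis_date"]),
        "patient_id",
    ].unique()
    labels["narrow"] = labels["broad"] & ~labels["patient_id"].isin(intervening)
    labels["window_days"] = window_days
    return labels[["patient_id", "broad", "narrow", "anchor_admission_date", "window_days"]]
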