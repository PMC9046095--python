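"""EP classification: boundary behaviour, the intervening-elective rule,
brute-force agreement, and the cohort-level invariants."""

import itertools
import warnings
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ep_routes as ep
from ep_routes.classify import Admission, classify_broad, classify_narrow

DX = date(2015, 6, 15)


def _adm(offset_days, kind):
    """Admission offset_days before the reference diagnosis date."""
    return Admission(DX - timedelta(days=offset_days), kind)


@pytest.mark.parametrize(
    "admissions,broad,narrow",
    [
        ([_adm(30, "emergency")], True, True),            # window edge inclusive
        ([_adm(31, "emergency")], False, False),          # just outside
        ([_adm(0, "emergency")], True, True),             # same-day admission
        ([_adm(10, "elective")], False, False),           # elective never triggers
        ([], False, False),
        # emergency d, elective d+10, diagnosis d+20
        ([_adm(20, "emergency"), _adm(10, "elective")], True, False),
        # elective before the emergency is not intervening
        ([_adm(20, "emergency"), _adm(25, "elective")], True, True),
        # second emergency clears the intervening elective
        ([_adm(20, "emergency"), _adm(15, "elective"), _adm(5, "emergency")], True, True),
        # same-day elective cannot be ordered, so it never intervenes
        ([_adm(20, "emergency"), _adm(20, "elective")], True, True),
        ([_adm(20, "emergency"), _adm(0, "elective")], True, True),
    ],
)
def test_definition_examples(admissions, broad, narrow):
    got_broad, anchor = classify_broad(DX, admissions)
    assert got_broad is broad
    assert (anchor is not None) is broad
    assert classify_narrow(DX, admissions) is narrow


def _oracle_narrow(dx, admissions, window):
    """Enumerate qualifying anchors directly from the definition."""
    for a in admissions:
        if a.admission_type != "emergency":
            continue
        off = (dx - a.admission_date).days
        if not 0 <= off <= window:
            continue
        if not any(
            b.admission_type == "elective"
            and a.admission_date < b.admission_date < dx
            for b in admissions
        ):
            return True
    return False


def test_exhaustive_histories_match_brute_force_oracle():
    """All <=3-admission histories over a grid of offsets and types agree
    with direct enumeration of qualifying anchors."""
    offsets = (-5, 0, 1, 15, 30, 31, 45)
    kinds = ("emergency", "elective")
    options = [_adm(o, k) for o in offsets for k in kinds]
    n_checked = 0
    for r in range(4):
        for combo in itertools.product(options, repeat=r):
            admissions = list(combo)
            broad, _ = classify_broad(DX, admissions)
            has_qualifying = any(
                a.admission_type == "emergency"
                and 0 <= (DX - a.admission_date).days <= 30
                for a in admissions
            )
            assert broad == has_qualifying
            assert classify_narrow(DX, admissions) == _oracle_narrow(DX, admissions, 30)
            n_checked += 1
    assert n_checked == 1 + 14 + 14**2 + 14**3


@given(
    st.lists(
        st.tuples(st.integers(-20, 60), st.sampled_from(["emergency", "elective"])),
        max_size=6,
    ),
    st.integers(1, 60),
    st.integers(-1000, 1000),
)
@settings(max_examples=300, derandomize=True, deadline=None)
def test_label_properties(history, window, shift):
    admissions = [_adm(o, k) for o, k in history]
    broad, anchor = classify_broad(DX, admissions, window)
    narrow = classify_narrow(DX, admissions, window)
    # narrow implies broad
    assert not (narrow and not broad)
    # monotone in window
    broad_wider, _ = classify_broad(DX, admissions, window + 10)
    assert broad_wider or not broad
    # translation invariance
    delta = timedelta(days=shift)
    shifted = [Admission(a.admission_date + delta, a.admission_type) for a in admissions]
    assert classify_broad(DX + delta, shifted, window) == (
        broad,
        anchor + delta if anchor else None,
    )
    assert classify_narrow(DX + delta, shifted, window) is narrow


def _random_cohort(rng, n):
    """n patients with 0-5 random admissions each around a random diagnosis."""
    dx = pd.Timestamp("2015-01-01") + pd.to_timedelta(rng.integers(0, 700, n), unit="D")
    tum = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)], "diagnosis_date": dx})
    rows = []
    for i in range(n):
        for _ in range(rng.integers(0, 6)):
            off = int(rng.integers(-30, 90))
            kind = "emergency" if rng.random() < 0.5 else "elective"
            rows.append((f"p{i}", dx[i] - pd.Timedelta(days=off), kind))
    adm = pd.DataFrame(rows, columns=["patient_id", "admission_date", "admission_type"])
    return tum, adm


def test_cohort_classification_invariants_on_random_histories():
    """10^4 randomised admission histories: narrow subset of broad, window
    monotonicity, translation invariance, and agreement with the scalar path."""
    rng = np.random.default_rng(42)
    tum, adm = _random_cohort(rng, 10_000)
    l30 = ep.classify_cohort(tum, adm, 30).set_index("patient_id")
    l60 = ep.classify_cohort(tum, adm, 60).set_index("patient_id")
    assert (~l30["narrow"] | l30["broad"]).all()
    assert (~l30["broad"] | l60["broad"]).all()

    shift = pd.Timedelta(days=123)
    l30s = ep.classify_cohort(
        tum.assign(diagnosis_date=tum["diagnosis_date"] + shift),
        adm.assign(admission_date=adm["admission_date"] + shift),
        30,
    ).set_index("patient_id")
    assert (l30s["broad"] == l30["broad"]).all()
    assert (l30s["narrow"] == l30["narrow"]).all()

    # vectorised path == per-patient scalar path on a subsample
    sample = tum.sample(300, random_state=1)
    for _, t in sample.iterrows():
        sub = adm[adm["patient_id"] == t["patient_id"]]
        admissions = [
            Admission(a.admission_date.date(), a.admission_type) for a in sub.itertuples()
        ]
        b, _ = classify_broad(t["diagnosis_date"].date(), admissions, 30)
        nrw = classify_narrow(t["diagnosis_date"].date(), admissions, 30)
        assert l30.loc[t["patient_id"], "broad"] == b
        assert l30.loc[t["patient_id"], "narrow"] == nrw


def test_orphan_admissions_warned_and_ignored():
    tum = pd.DataFrame(
        {"patient_id": ["p1"], "diagnosis_date": [pd.Timestamp("2015-06-15")]}
    )
    adm = pd.DataFrame(
        {
            "patient_id": ["p1", "ghost"],
            "admission_date": [pd.Timestamp("2015-06-10")] * 2,
            "admission_type": ["emergency", "emergency"],
        }
    )
    with pytest.warns(UserWarning, match="unknown patients"):
        labels = ep.classify_cohort(tum, adm)
    assert len(labels) == 1 and labels["broad"].iloc[0]


def test_anchor_is_latest_qualifying_emergency():
    admissions = [_adm(25, "emergency"), _adm(3, "emergency")]
    _, anchor = classify_broad(DX, admissions)
    assert anchor == DX - timedelta(days=3)
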