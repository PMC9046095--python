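"""The aggregate-only federated contract: bundles, suppression, collation."""

import numpy as np
import pandas as pd
import pytest

import ep_routes as ep
from ep_routes.federated import (
    FORBIDDEN_COLUMNS,
    AggregateBundle,
    SchemaViolationError,
    _suppress_small_cells,
)


@pytest.fixture(scope="module")
def bundles(small_config, small_cohort):
    tum, adm = small_cohort
    out = []
    for j in small_config.jurisdictions[:3]:
        t = tum[tum["jurisdiction"] == j.name]
        a = adm[adm["patient_id"].isin(t["patient_id"])]
        out.append(
            ep.run_jurisdiction(
                t, a, j.definition_type,
                suppression_threshold=5,
                config_hash=small_config.config_hash(),
                seed=small_config.seed,
            )
        )
    return out


def test_bundle_completeness(bundles):
    b = bundles[0]
    by_site = b.stratum_summaries[b.stratum_summaries["stratified_by"] == "site"]
    assert len(by_site) == 8
    assert (
        (b.estimates["model"] == "mortality_adj_stage")
        & (b.estimates["term"] == "ep_status=True")
    ).any()


def test_no_patient_level_columns_in_bundles(bundles):
    for b in bundles:
        assert not (FORBIDDEN_COLUMNS & set(b.stratum_summaries.columns))
        assert not (FORBIDDEN_COLUMNS & set(b.estimates.columns))
        b.validate()


def test_schema_scan_rejects_patient_level_table(bundles):
    bad = AggregateBundle(
        jurisdiction="X",
        definition_type="broad",
        window_days=30,
        stratum_summaries=pd.DataFrame({"patient_id": ["p1"], "n": [1]}),
        estimates=bundles[0].estimates,
    )
    with pytest.raises(SchemaViolationError):
        bad.validate()


def test_bundle_round_trip(bundles, tmp_path):
    b = bundles[0]
    b.to_dir(tmp_path / "b0")
    again = AggregateBundle.from_dir(tmp_path / "b0")
    again.to_dir(tmp_path / "b1")
    for name in ("stratum_summaries.csv", "estimates.csv", "manifest.json"):
        assert (tmp_path / "b0" / name).read_bytes() == (tmp_path / "b1" / name).read_bytes()


def test_small_cell_suppression_enumeration():
    summaries = pd.DataFrame(
        {
            "n": [100, 100, 100, 3, 100],
            "k": [0, 3, 50, 3, 98],
            "pct": [0.0, 3.0, 50.0, 100.0, 98.0],
            "ci_low": 0.0,
            "ci_high": 1.0,
        }
    )
    out = _suppress_small_cells(summaries, threshold=5)
    # k=0 unmasked (nothing to disclose), k=3 masked, k=50 fine,
    # n=k=3 masked? k=3>0 and <5 -> masked; k=98 has n-k=2 -> masked
    assert out["masked"].tolist() == [False, True, False, True, True]
    assert out.loc[out["masked"], "k"].isna().all()
    assert out.loc[~out["masked"], "k"].notna().all()


def test_zero_threshold_masks_nothing(bundles, small_cohort, small_config):
    tum, adm = small_cohort
    j = small_config.jurisdictions[0]
    t = tum[tum["jurisdiction"] == j.name]
    a = adm[adm["patient_id"].isin(t["patient_id"])]
    b = ep.run_jurisdiction(t, a, j.definition_type, suppression_threshold=0)
    assert not b.stratum_summaries["masked"].any()


def test_collate_matrix_and_order_invariance(bundles):
    central = ep.collate(bundles)
    mat = central["ep_percentage_matrix"]
    assert mat.shape == (3, 8)
    flipped = ep.collate(list(reversed(bundles)))
    pd.testing.assert_frame_equal(mat, flipped["ep_percentage_matrix"])
    pd.testing.assert_frame_equal(central["meta_ready"], flipped["meta_ready"])


def test_collate_refuses_mixed_windows(bundles):
    other = AggregateBundle(
        jurisdiction="W60",
        definition_type="broad",
        window_days=60,
        stratum_summaries=bundles[0].stratum_summaries,
        estimates=bundles[0].estimates,
    )
    with pytest.raises(ValueError, match="window"):
        ep.collate(bundles + [other])


def test_collate_flags_injected_inconsistency(small_config, small_cohort):
    tum, adm = small_cohort
    j = small_config.jurisdictions[0]
    t = tum[tum["jurisdiction"] == j.name]
    a = adm[adm["patient_id"].isin(t["patient_id"])]
    b = ep.run_jurisdiction(t, a, j.definition_type, suppression_threshold=0)
    tampered = b.stratum_summaries.copy()
    site_rows = tampered["stratified_by"] == "site"
    tampered.loc[site_rows, "n"] = tampered.loc[site_rows, "n"] + 10
    bad = AggregateBundle(
        jurisdiction=b.jurisdiction,
        definition_type=b.definition_type,
        window_days=b.window_days,
        stratum_summaries=tampered,
        estimates=b.estimates,
    )
    central = ep.collate([bad])
    row = central["consistency"].set_index("jurisdiction").loc[b.jurisdiction]
    assert not row["ok"]


def test_end_to_end_equals_stagewise(small_config, small_cohort, bundles):
    """Composing the stages by hand reproduces run_jurisdiction + collate."""
    tum, adm = small_cohort
    central = ep.collate(bundles)
    for j in small_config.jurisdictions[:3]:
        t = tum[tum["jurisdiction"] == j.name]
        a = adm[adm["patient_id"].isin(t["patient_id"])]
        included, _ = ep.apply_inclusion_criteria(t)
        labels = ep.classify_cohort(included, a)
        merged = included.merge(
            labels.drop(columns=["anchor_admission_date"]), on="patient_id"
        )
        merged = ep.add_mortality_indicators(merged)
        manual = ep.ep_percentage_by_stratum(merged, ["site"], definition=j.definition_type)
        got = central["ep_percentage_matrix"].loc[j.name]
        for _, r in manual.iterrows():
            assert got[r["site"]] == pytest.approx(r["pct"])
        est = ep.run_jurisdiction_models(merged, horizons=("12m",), definition=j.definition_type)
        e = est[(est["model"] == "mortality_adj_stage") & (est["term"] == "ep_status=True")]
        mr = central["meta_ready"].set_index("jurisdiction").loc[j.name]
        assert mr["log_or"] == pytest.approx(float(e["log_or"].iloc[0]), rel=1e-9)


def test_collated_estimates_pool_like_direct_pooling(bundles):
    central = ep.collate(bundles)
    ests = [
        ep.StudyEstimate(r.jurisdiction, r.log_or, r.se, r.definition_type)
        for r in central["meta_ready"].itertuples()
    ]
    res = ep.pool_random_effects(ests)
    direct = ep.pool_random_effects(
        [
            ep.StudyEstimate(
                b.jurisdiction,
                float(
                    b.estimates.loc[
                        (b.estimates["model"] == "mortality_adj_stage")
                        & (b.estimates["term"] == "ep_status=True"),
                        "log_or",
                    ].iloc[0]
                ),
                float(
                    b.estimates.loc[
                        (b.estimates["model"] == "mortality_adj_stage")
                        & (b.estimates["term"] == "ep_status=True"),
                        "se",
                    ].iloc[0]
                ),
                b.definition_type,
            )
            for b in bundles
        ]
    )
    assert res.pooled["overall"].log_or == pytest.approx(
        direct.pooled["overall"].log_or, rel=1e-12
    )
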