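"""The federated-analysis contract: aggregate-only data exchange.

Each jurisdiction runs the full pipeline locally (eligibility -> EP
classification -> stratified summaries -> regression models) and exports
only an :class:`AggregateBundle` — stratum counts/percentages and model
estimates, never patient-level rows.  Small cells below a suppression
threshold are masked before export.  The central side collates bundles
into the cross-jurisdiction tables and a meta-analysis-ready estimate
table.  "Federated" here means this aggregate-only contract; there is
no networking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import classify_cohort
from .cohort import apply_inclusion_criteria
from .descriptive import ep_percentage_by_stratum
from .models import add_mortality_indicators, run_jurisdiction_models

SCHEMA_VERSION = "1.0"

#: Column names that would carry patient-level granularity; forbidden in
#: any exported table.
FORBIDDEN_COLUMNS = frozenset(
    {"patient_id", "diagnosis_date", "death_date", "censor_date", "admission_date"}
)


class SchemaViolationError(ValueError):
    """An exported table violates the aggregate-only schema."""


@dataclass
class AggregateBundle:
    jurisdiction: str
    definition_type: str
    window_days: int
    stratum_summaries: pd.DataFrame
    estimates: pd.DataFrame
    schema_version: str = SCHEMA_VERSION
    config_hash: str = ""
    seed: int | None = None
    n_included: int = 0
    suppression_threshold: int = 0

    def validate(self) -> None:
        for name, table in (("stratum_summaries", self.stratum_summaries),
                            ("estimates", self.estimates)):
            bad = FORBIDDEN_COLUMNS & set(table.columns)
            if bad:
                raise SchemaViolationError(
                    f"{name} carries patient-level column(s): {sorted(bad)}"
                )
        if self.definition_type not in ("broad", "narrow"):
            raise SchemaViolationError(f"unknown definition_type {self.definition_type!r}")

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.validate()
        self.stratum_summaries.to_csv(path / "stratum_summaries.csv", index=False)
        self.estimates.to_csv(path / "estimates.csv", index=False)
        manifest = {
            "jurisdiction": self.jurisdiction,
            "definition_type": self.definition_type,
            "window_days": self.window_days,
            "schema_version": self.schema_version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_included": self.n_included,
            "suppression_threshold": self.suppression_threshold,
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def from_dir(cls, path) -> "AggregateBundle":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        if manifest.get("schema_version") != SCHEMA_VERSION:
            raise SchemaViolationError(
                f"unrecognised schema_version {manifest.get('schema_version')!r}"
            )
        return cls(
            jurisdiction=manifest["jurisdiction"],
            definition_type=manifest["definition_type"],
            window_days=manifest["window_days"],
            stratum_summaries=pd.read_csv(
                path / "stratum_summaries.csv", float_precision="round_trip"
            ),
            estimates=pd.read_csv(path / "estimates.csv", float_precision="round_trip"),
            schema_version=manifest["schema_version"],
            config_hash=manifest.get("config_hash", ""),
            seed=manifest.get("seed"),
            n_included=manifest.get("n_included", 0),
            suppression_threshold=manifest.get("suppression_threshold", 0),
        )


def _suppress_small_cells(summaries: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Mask cells whose numerator or complement is positive but < threshold."""
    out = summaries.copy()
    out["masked"] = False
    if threshold <= 0:
        return out
    k, n = out["k"], out["n"]
    small = ((k > 0) & (k < threshold)) | (((n - k) > 0) & ((n - k) < threshold))
    out.loc[small, ["k", "pct", "ci_low", "ci_high"]] = np.nan
    out.loc[small, "masked"] = True
    return out


def run_jurisdiction(
    tumours: pd.DataFrame,
    admissions: pd.DataFrame,
    definition_type: str,
    window_days: int = 30,
    suppression_threshold: int = 5,
    horizons: tuple[str, ...] = ("12m",),
    study_period: tuple[int, int] = (2012, 2017),
    config_hash: str = "",
    seed: int | None = None,
) -> AggregateBundle:
    """Run the whole local pipeline for one jurisdiction, emit aggregates.

    Deterministic given its inputs: eligibility filtering, EP labelling
    at ``window_days``, stratified EP percentages (by site, and by each
    demographic variable), and the logistic model battery, all reduced
    to aggregate tables with small-cell suppression applied.
    """
    jurisdiction = str(tumours["jurisdiction"].iloc[0])
    included, report = apply_inclusion_criteria(tumours, study_period=study_period)
    labels = classify_cohort(included, admissions, window_days=window_days)
    labelled = included.merge(
        labels.drop(columns=["anchor_admission_date"]), on="patient_id"
    )
    labelled = add_mortality_indicators(labelled)

    definition = definition_type
    strata = []
    for by in (["site"], ["site", "age_group"], ["site", "sex"],
               ["site", "stage"], ["site", "year"]):
        s = ep_percentage_by_stratum(labelled, by, definition=definition)
        s.insert(0, "stratified_by", "+".join(by))
        strata.append(s)
    summaries = pd.concat(strata, ignore_index=True)
    summaries = _suppress_small_cells(summaries, suppression_threshold)
    summaries.insert(0, "jurisdiction", jurisdiction)
    summaries["window_days"] = window_days

    estimates = run_jurisdiction_models(labelled, horizons=horizons,
                                        definition=definition)
    bundle = AggregateBundle(
        jurisdiction=jurisdiction,
        definition_type=definition_type,
        window_days=window_days,
        stratum_summaries=summaries,
        estimates=estimates,
        config_hash=config_hash,
        seed=seed,
        n_included=report.n_included,
        suppression_threshold=suppression_threshold,
    )
    bundle.validate()
    return bundle


def collate(bundles: list[AggregateBundle]) -> dict:
    """Merge jurisdiction bundles into central tables.

    Returns a dict with the jurisdiction x site EP percentage matrix,
    the 12-month mortality estimate table, a meta-analysis-ready table
    of EP-mortality log-ORs, and a consistency report (per-site stratum
    sums versus jurisdiction totals).  Refuses to pool bundles computed
    at different window lengths.
    """
    if not bundles:
        raise ValueError("no bundles to collate")
    windows = {b.window_days for b in bundles}
    if len(windows) > 1:
        raise ValueError(f"mixed window_days across bundles: {sorted(windows)}")
    versions = {b.schema_version for b in bundles}
    if versions != {SCHEMA_VERSION}:
        raise SchemaViolationError(f"incompatible schema versions: {sorted(versions)}")
    for b in bundles:
        b.validate()

    ordered = sorted(bundles, key=lambda b: b.jurisdiction)

    site_rows = []
    consistency = []
    for b in ordered:
        s = b.stratum_summaries
        by_site = s[s["stratified_by"] == "site"]
        for _, r in by_site.iterrows():
            site_rows.append(
                (b.jurisdiction, b.definition_type, r["site"], r["n"], r["k"], r["pct"])
            )
        # Internal consistency: age-stratified sums must reproduce site totals
        # (masked cells excluded from the check, with a flag).
        by_age = s[s["stratified_by"] == "site+age_group"]
        if by_age["masked"].any():
            consistency.append(
                {"jurisdiction": b.jurisdiction, "check": "site_sum",
                 "ok": True, "note": "masked cells excluded from sum check"}
            )
        else:
            merged = by_age.groupby("site")[["n", "k"]].sum().join(
                by_site.set_index("site")[["n", "k"]], rsuffix="_total"
            )
            ok = bool(
                np.allclose(merged["n"], merged["n_total"])
                and np.allclose(merged["k"], merged["k_total"])
            )
            consistency.append(
                {"jurisdiction": b.jurisdiction, "check": "site_sum", "ok": ok,
                 "note": "" if ok else "stratum sums do not match totals"}
            )

    site_table = pd.DataFrame(
        site_rows, columns=["jurisdiction", "definition_type", "site", "n", "k", "pct"]
    )
    pct_matrix = site_table.pivot(index="jurisdiction", columns="site", values="pct")

    est_frames = []
    for b in ordered:
        e = b.estimates.copy()
        e["definition_type"] = b.definition_type
        est_frames.append(e)
    estimates = pd.concat(est_frames, ignore_index=True)

    meta_ready = estimates[
        (estimates["model"] == "mortality_adj_stage")
        & (estimates["horizon"] == "12m")
        & (estimates["term"] == "ep_status=True")
        & estimates["converged"].astype(bool)
    ][["jurisdiction", "definition_type", "log_or", "se"]].reset_index(drop=True)

    return {
        "ep_percentage_matrix": pct_matrix,
        "site_table": site_table,
        "estimates": estimates,
        "meta_ready": meta_ready,
        "consistency": pd.DataFrame(consistency),
    }
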