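import pytest

import ep_routes as ep
from ep_routes.config import JurisdictionSpec


@pytest.fixture(scope="session")
def small_config():
    return ep.default_config(seed=11, n_patients=3000)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ep.generate_cohort(small_config)


@pytest.fixture(scope="session")
def labelled(small_cohort):
    """Included tumours joined to EP labels and mortality indicators."""
    tum, adm = small_cohort
    included, _ = ep.apply_inclusion_criteria(tum)
    labels = ep.classify_cohort(included, adm)
    merged = included.merge(labels.drop(columns=["anchor_admission_date"]), on="patient_id")
    return ep.add_mortality_indicators(merged)


def single_jurisdiction_config(seed, n, name="Solo", definition_type="broad",
                               stage_missing_frac=0.0):
    """One fully-staged jurisdiction, default mixes and models."""
    cfg = ep.default_config(seed=seed, n_patients=n)
    cfg.jurisdictions = [
        JurisdictionSpec(name=name, definition_type=definition_type,
                         n_patients=n, stage_missing_frac=stage_missing_frac)
    ]
    cfg.seed = seed
    return cfg
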