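"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from rtbi_lca import (
    SimConfig,
    apply_case_definitions,
    emit_claims,
    simulate_population,
)


@pytest.fixture(scope="session")
def calibration_sim():
    """A fully-incident, uncensored cohort with no early noise: the setting
    in which the generated definitions' empirical Se/Sp must match the
    configured values against latent truth."""
    cfg = SimConfig(
        n_patients=60_000,
        incident_prob_by_age=(1.0, 1.0, 1.0),
        censor_prob=0.0,
        followup_noise_rate=0.0,
        seed=1234,
    )
    patients, truth = simulate_population(cfg)
    claims = emit_claims(patients, truth, cfg)
    return cfg, patients, truth, claims


@pytest.fixture(scope="session")
def noisy_sim():
    """Default conditions (early follow-up noise on) on a fully-incident
    uncensored cohort, with case definitions applied; used by the
    sensitivity-analysis and median-time checks."""
    cfg = SimConfig(
        n_patients=40_000,
        incident_prob_by_age=(1.0, 1.0, 1.0),
        censor_prob=0.0,
        seed=77,
    )
    patients, truth = simulate_population(cfg)
    claims = emit_claims(patients, truth, cfg)
    incident = truth[truth["is_incident_tbi"]].reset_index(drop=True)
    hits = apply_case_definitions(claims, incident[["patient_id", "index_date"]])
    return cfg, patients, truth, claims, incident, hits


@pytest.fixture
def tiny_claims():
    """Hand-built claims for window/pairing edge cases (index at day 0)."""

    def build(rows):
        base = pd.Timestamp("2005-01-01")
        return pd.DataFrame(
            {
                "patient_id": [r[0] for r in rows],
                "service_date": [base + pd.Timedelta(days=r[1]) for r in rows],
                "source": [r[2] for r in rows],
                "code": [r[3] for r in rows],
                "code_system": [r[4] for r in rows],
            }
        )

    return build


@pytest.fixture
def tiny_index():
    def build(patient_ids):
        return pd.DataFrame(
            {
                "patient_id": patient_ids,
                "index_date": pd.Timestamp("2005-01-01"),
            }
        )

    return build
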