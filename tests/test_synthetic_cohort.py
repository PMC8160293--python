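"""Generator correctness: stratum calibration, determinism, conservation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rtbi_lca import SimConfig, draw_incident_cohorts, emit_claims, simulate_population
from rtbi_lca.case_ascertainment import DEFINITIONS, apply_case_definitions
from rtbi_lca.errors import ArgumentError, ConfigurationError


def test_zero_incident_rate_yields_no_cases():
    cfg = SimConfig(n_patients=2_000, incident_prob_by_age=(0.0, 0.0, 0.0), seed=1)
    _, truth = simulate_population(cfg)
    assert not truth["is_incident_tbi"].any()
    assert not truth["has_recurrence"].any()


def test_saturated_recurrence_without_censoring():
    cfg = SimConfig(
        n_patients=2_000,
        incident_prob_by_age=(1.0, 1.0, 1.0),
        recurrence_rate_by_age_severity=((1.0, 1.0),) * 3,
        censor_prob=0.0,
        seed=2,
    )
    _, truth = simulate_population(cfg)
    assert truth["is_incident_tbi"].all()
    assert truth["has_recurrence"].all()


def test_recurrence_fraction_matches_binomial_oracle():
    """At 5% in every stratum (no sex effect), the realised recurrence
    fraction among incident cases must sit within 3 binomial SE of 5%."""
    rate = 0.05
    cfg = SimConfig(
        n_patients=100_000,
        incident_prob_by_age=(1.0, 1.0, 1.0),
        recurrence_rate_by_age_severity=((rate, rate),) * 3,
        sex_log_odds_ratio=0.0,
        censor_prob=0.0,
        seed=3,
    )
    _, truth = simulate_population(cfg)
    frac = truth["has_recurrence"].mean()
    se = np.sqrt(rate * (1 - rate) / len(truth))
    assert abs(frac - rate) < 3 * se


def test_sex_marginal_rate_honoured_despite_log_odds_shift():
    """The configured stratum rate is the both-sexes marginal; the male
    odds shift must not move it."""
    cfg = SimConfig(
        n_patients=100_000,
        incident_prob_by_age=(1.0, 1.0, 1.0),
        recurrence_rate_by_age_severity=((0.08, 0.08),) * 3,
        sex_log_odds_ratio=np.log(2.0),
        censor_prob=0.0,
        seed=4,
    )
    patients, truth = simulate_population(cfg)
    frac = truth["has_recurrence"].mean()
    se = np.sqrt(0.08 * 0.92 / len(truth))
    assert abs(frac - 0.08) < 3 * se
    # and the male/female gap has the configured direction
    m = truth.merge(patients[["patient_id", "sex"]], on="patient_id")
    assert (
        m.loc[m["sex"] == "M", "has_recurrence"].mean()
        > m.loc[m["sex"] == "F", "has_recurrence"].mean()
    )


def test_determinism_byte_identical():
    cfg = SimConfig(n_patients=3_000, seed=99)
    p1, t1 = simulate_population(cfg)
    p2, t2 = simulate_population(cfg)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(t1, t2)
    c1 = emit_claims(p1, t1, cfg)
    c2 = emit_claims(p2, t2, cfg)
    pd.testing.assert_frame_equal(c1, c2)


def test_truth_conservation_invariants():
    cfg = SimConfig(n_patients=20_000, incident_prob_by_age=(1.0, 1.0, 1.0), seed=5)
    patients, truth = simulate_population(cfg)
    rec = truth["has_recurrence"]
    assert truth.loc[rec, "is_incident_tbi"].all()
    assert truth.loc[rec, "recurrence_day"].notna().all()
    assert truth.loc[~rec, "recurrence_day"].isna().all()
    days = truth.loc[rec, "recurrence_day"].astype(int)
    assert days.between(7, 365).all()
    # claims never precede entry nor follow exit
    claims = emit_claims(patients, truth, cfg)
    m = claims.merge(patients[["patient_id", "entry_date", "exit_date"]], on="patient_id")
    assert (m["service_date"] >= m["entry_date"]).all()
    assert (m["service_date"] <= m["exit_date"]).all()


@pytest.mark.parametrize(
    "field, value, fragment",
    [
        ("censor_prob", 1.7, "censor_prob"),
        ("severity_prob", -0.1, "severity_prob"),
        ("age_group_probs", (0.5, 0.4, 0.2), "sum to 1"),
        ("incident_prob_by_age", (0.5, 1.4, 0.2), "incident_prob_by_age"),
    ],
)
def test_invalid_configuration_names_the_field(field, value, fragment):
    cfg = dataclasses.replace(SimConfig(), **{field: value})
    with pytest.raises(ConfigurationError, match=fragment):
        cfg.validate()


def test_non_identifiable_definition_rejected():
    cfg = dataclasses.replace(
        SimConfig(), se_by_definition=(0.1, 0.42, 0.14, 0.79),
        sp_by_definition=(0.6, 0.99, 0.99, 0.99),
    )
    with pytest.raises(ConfigurationError, match="identifiability"):
        cfg.validate()


def test_marginal_se_sp_calibration(calibration_sim):
    """With no follow-up noise, each definition's empirical Se and Sp
    (measured against latent truth after ascertainment) match the
    configured operating points within 3 binomial SE."""
    cfg, patients, truth, claims = calibration_sim
    incident = truth[truth["is_incident_tbi"]]
    hits = apply_case_definitions(claims, incident[["patient_id", "index_date"]])
    m = hits.merge(truth[["patient_id", "has_recurrence"]], on="patient_id")
    n1 = int(m["has_recurrence"].sum())
    n0 = len(m) - n1
    for j, d in enumerate(DEFINITIONS):
        se_emp = m.loc[m["has_recurrence"], d].mean()
        sp_emp = 1.0 - m.loc[~m["has_recurrence"], d].mean()
        se_cfg = cfg.se_by_definition[j]
        sp_cfg = cfg.sp_by_definition[j]
        assert abs(se_emp - se_cfg) < 3 * np.sqrt(se_cfg * (1 - se_cfg) / n1), d
        assert abs(sp_emp - sp_cfg) < 3 * np.sqrt(sp_cfg * (1 - sp_cfg) / n0), d


def test_false_positive_rate_matches_binomial_oracle(calibration_sim):
    """1 - Sp is the total false-positive probability per definition."""
    cfg, patients, truth, claims = calibration_sim
    incident = truth[truth["is_incident_tbi"]]
    hits = apply_case_definitions(claims, incident[["patient_id", "index_date"]])
    m = hits.merge(truth[["patient_id", "has_recurrence"]], on="patient_id")
    non = m[~m["has_recurrence"]]
    rate = non["outpatient"].mean()
    expect = 1.0 - cfg.sp_by_definition[0]
    assert abs(rate - expect) < 3 * np.sqrt(expect * (1 - expect) / len(non))


def test_early_noise_concentrates_in_first_month(noisy_sim):
    """With the default early-noise rate, qualifying claims among
    non-recurrent patients are denser in days 7-30 than in days 31-54."""
    cfg, patients, truth, claims, incident, hits = noisy_sim
    m = hits.merge(truth[["patient_id", "has_recurrence"]], on="patient_id")
    days = m.loc[~m["has_recurrence"], "first_hit_day"].dropna().astype(int)
    early = int(((days >= 7) & (days <= 30)).sum())
    later = int(((days >= 31) & (days <= 54)).sum())
    assert early > later


def test_cohort_draws_inclusion_frequency():
    cfg = SimConfig(n_patients=200, incident_prob_by_age=(1.0, 1.0, 1.0),
                    censor_prob=0.0, membership_mean=0.5,
                    membership_concentration=1e9, seed=6)
    _, truth = simulate_population(cfg)
    mats = draw_incident_cohorts(truth, n_cohorts=1000, seed=7)
    freq = mats.mean(axis=0)
    se = np.sqrt(0.5 * 0.5 / 1000)
    assert np.all(np.abs(freq - 0.5) < 4 * se)


def test_cohorts_identical_when_membership_certain():
    cfg = SimConfig(n_patients=500, membership_mean=1.0, seed=8)
    _, truth = simulate_population(cfg)
    mats = draw_incident_cohorts(truth, n_cohorts=5, seed=9)
    assert (mats == mats[0][None, :]).all()
    assert (mats[0] == truth["is_incident_tbi"].to_numpy()).all()


def test_cohort_count_precondition():
    cfg = SimConfig(n_patients=50, seed=10)
    _, truth = simulate_population(cfg)
    with pytest.raises(ArgumentError):
        draw_incident_cohorts(truth, n_cohorts=0)
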