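"""Synthetic administrative-claims cohorts with latent recurrent-TBI truth.

The real analysis runs on provincial health-insurance claims that cannot
be shared, so this module generates populations with the same statistical
structure: a dynamic cohort of patients in three age groups, latent index
TBI episodes in two severity groupings ("mildest/more severe" vs "most
severe"), latent recurrence within one year of the index event, and a
claim stream in which each of the four surveillance case definitions fires
with configurable sensitivity on true recurrences and produces false
positives on non-recurrent follow-up — with the false-positive mass
concentrated in the first month after the index event, where follow-up
care masquerades as recurrence.

Three tables are produced (all plain pandas DataFrames, CSV-serialisable):

* patients — ``patient_id, sex, age_group, entry_date, exit_date``
* truth    — ``patient_id, is_incident_tbi, incident_membership_prob,
  index_date, severity, has_recurrence, recurrence_day``
* claims   — ``patient_id, service_date, source, code, code_system``

``incident_membership_prob`` emulates the posterior probability, from an
upstream incident-TBI latent class model, that the patient truly had an
index TBI; drawing Bernoulli cohorts from these probabilities reproduces
the predicted-cohort mechanism by which upstream uncertainty is carried
into the recurrence analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .case_ascertainment import DEFINITIONS
from .errors import ArgumentError, ConfigurationError

AGE_GROUPS = ("children", "adults", "elderly")
SEVERITIES = ("mildest_more_severe", "most_severe")

# Example diagnostic codes drawn by the claim emitter. TBI codes are
# intracranial injury / skull fracture families; trauma codes are non-TBI
# injuries (sprains, contusions, superficial injuries) that satisfy the
# any-trauma families 8XX/91X/92X/93X without being TBI codes.
_ICD9_TBI_CODES = ("8500", "8509", "80100", "85220", "95901", "8540")
_ICD10_TBI_CODES = ("S060", "S0990", "S027", "T905")
_TRAUMA_CODES = ("8470", "9100", "9200", "9240", "9330")
_RADIOLOGY_CODES = ("08258", "08259", "08570", "08010", "08013")

#: DAD coding switched from ICD-9 to ICD-10 at this calendar year.
_DAD_ICD10_FROM_YEAR = 2007


@dataclass(frozen=True)
class SimConfig:
    """Data-generating conditions for one synthetic study.

    Defaults mirror the surveillance setting the package targets: a
    15-year dynamic cohort, age mix and male fractions echoing the index
    TBI cohorts of the motivating study, per-stratum one-year recurrence
    risks around 1.7/3.6/9.0 per 100 for children/adults/elderly with a
    "most severe" : "mildest/more severe" risk ratio per age group, male
    sex raising recurrence odds by ~1.4 in children/adults, and
    definition operating points (Se, Sp) at the adult estimates of the
    motivating analysis. ``recurrence_rate_by_age_severity`` is the
    *marginal* (both-sexes) risk; the generator back-solves the female
    baseline so the configured marginal is honoured whatever
    ``sex_log_odds_ratio`` is.
    """

    n_patients: int = 20_000
    study_window: tuple[str, str] = ("2000-01-01", "2014-12-31")
    age_group_probs: tuple[float, float, float] = (0.20, 0.60, 0.20)
    sex_prob_by_age: tuple[float, float, float] = (0.603, 0.567, 0.379)
    incident_prob_by_age: tuple[float, float, float] = (0.10, 0.045, 0.085)
    severity_prob: float = 0.10
    recurrence_rate_by_age_severity: tuple[tuple[float, float], ...] = (
        (0.0158, 0.0266),   # children: marginal 1.69/100, S:M ratio 1.685
        (0.0292, 0.0940),   # adults:   marginal 3.57/100, S:M ratio 3.219
        (0.0898, 0.0944),   # elderly:  marginal 9.03/100, S:M ratio 1.051
    )
    sex_log_odds_ratio: float = math.log(1.4)
    recurrence_median_days_by_age: tuple[float, float, float] = (120.0, 75.0, 109.0)
    se_by_definition: tuple[float, float, float, float] = (0.19, 0.42, 0.14, 0.79)
    sp_by_definition: tuple[float, float, float, float] = (
        0.9516, 0.9898, 0.9876, 0.9874,
    )
    followup_noise_rate: float = 0.006
    followup_noise_decay: float = 0.85
    membership_mean: float = 0.85
    membership_concentration: float = 25.0
    censor_prob: float = 0.10
    seed: int = 20140101

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first bad field."""
        probs = {
            "severity_prob": self.severity_prob,
            "sex_log_odds_ratio": None,  # unconstrained, listed for clarity
            "followup_noise_rate": self.followup_noise_rate,
            "followup_noise_decay": self.followup_noise_decay,
            "membership_mean": self.membership_mean,
            "censor_prob": self.censor_prob,
        }
        for name, value in probs.items():
            if value is not None and not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("age_group_probs", "sex_prob_by_age", "incident_prob_by_age"):
            vec = getattr(self, name)
            if len(vec) != len(AGE_GROUPS):
                raise ConfigurationError(f"{name} must have {len(AGE_GROUPS)} entries")
            if any(not (0.0 <= p <= 1.0) for p in vec):
                raise ConfigurationError(f"{name} entries must be in [0, 1], got {vec}")
        if abs(sum(self.age_group_probs) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"age_group_probs must sum to 1, got {sum(self.age_group_probs)}"
            )
        for g, row in enumerate(self.recurrence_rate_by_age_severity):
            if any(not (0.0 <= p <= 1.0) for p in row):
                raise ConfigurationError(
                    f"recurrence_rate_by_age_severity[{g}] must be in [0, 1], got {row}"
                )
        for name in ("se_by_definition", "sp_by_definition"):
            vec = getattr(self, name)
            if len(vec) != len(DEFINITIONS):
                raise ConfigurationError(f"{name} must have {len(DEFINITIONS)} entries")
            if any(not (0.0 <= p <= 1.0) for p in vec):
                raise ConfigurationError(f"{name} entries must be in [0, 1], got {vec}")
        for j, (se, sp) in enumerate(
            zip(self.se_by_definition, self.sp_by_definition)
        ):
            if se + sp <= 1.0:
                raise ConfigurationError(
                    f"se_by_definition[{j}] + sp_by_definition[{j}] must exceed 1 "
                    f"for class identifiability, got {se} + {sp}"
                )
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")

    @property
    def study_days(self) -> int:
        start, end = (pd.Timestamp(d) for d in self.study_window)
        return int((end - start).days)


def _female_baseline(marginal: float, male_frac: float, log_or: float) -> float:
    """Female recurrence probability whose sex mixture hits ``marginal``."""
    if marginal <= 0.0:
        return 0.0
    if marginal >= 1.0:
        return 1.0
    if log_or == 0.0 or male_frac in (0.0,):
        return marginal

    def gap(pf: float) -> float:
        pm = expit(logit(pf) + log_or)
        return (1.0 - male_frac) * pf + male_frac * pm - marginal

    return brentq(gap, 1e-12, 1.0 - 1e-12)


def _truncated_exp_days(
    rng: np.random.Generator, n: int, median: float, lo: int = 7, hi: int = 365
) -> np.ndarray:
    """Recurrence days: discretized exponential truncated to [lo, hi].

    The scale is set so the *untruncated* median equals ``median``;
    truncation to the one-year window shifts the realised median slightly.
    """
    scale = median / math.log(2.0)
    u_lo, u_hi = 1.0 - math.exp(-lo / scale), 1.0 - math.exp(-hi / scale)
    u = rng.uniform(u_lo, u_hi, size=n)
    days = np.rint(-scale * np.log1p(-u)).astype(int)
    return np.clip(days, lo, hi)


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the patient roster and the latent truth table.

    Deterministic for a fixed config (including seed). Latent recurrence
    is assigned independently of censoring; a claim stream can only
    *reveal* a recurrence while the patient is still in the cohort, which
    is how administrative follow-up truncation operates.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_patients
    start = pd.Timestamp(config.study_window[0])
    total_days = config.study_days

    age_idx = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(config.age_group_probs))
    male = rng.random(n) < np.asarray(config.sex_prob_by_age)[age_idx]
    censored = rng.random(n) < config.censor_prob
    exit_days = np.where(
        censored, rng.integers(1, total_days + 1, size=n), total_days
    )

    incident = rng.random(n) < np.asarray(config.incident_prob_by_age)[age_idx]
    # Index dates leave a full 366-day follow-up window inside the study.
    index_day = rng.integers(0, max(total_days - 366, 1), size=n)
    # an index TBI is only observable while the patient is in the cohort;
    # under censoring the realised incident fraction is therefore slightly
    # below the configured probability (exact when censor_prob = 0)
    incident &= index_day < exit_days
    severe = rng.random(n) < config.severity_prob

    # Recurrence probability: female baseline back-solved per stratum so the
    # configured marginal holds, then the male log-odds shift applied.
    rates = np.asarray(config.recurrence_rate_by_age_severity)
    p_rec = np.zeros(n)
    for g in range(len(AGE_GROUPS)):
        for s in range(2):
            sel = (age_idx == g) & (severe == bool(s))
            if not sel.any():
                continue
            pf = _female_baseline(
                rates[g, s], config.sex_prob_by_age[g], config.sex_log_odds_ratio
            )
            if pf in (0.0, 1.0):
                p_rec[sel] = pf
            else:
                eta = logit(pf) + config.sex_log_odds_ratio * male[sel]
                p_rec[sel] = expit(eta)
    has_rec = incident & (rng.random(n) < p_rec)

    rec_day = np.full(n, -1)
    for g, median in enumerate(config.recurrence_median_days_by_age):
        sel = has_rec & (age_idx == g)
        rec_day[sel] = _truncated_exp_days(rng, int(sel.sum()), median)

    if config.membership_mean >= 1.0:
        member_p = np.ones(n)
    else:
        k = config.membership_concentration
        member_p = rng.beta(
            config.membership_mean * k, (1.0 - config.membership_mean) * k, size=n
        )
    member_p = np.where(incident, member_p, 0.0)

    pid = np.array([f"P{i:07d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": np.where(male, "M", "F"),
            "age_group": np.asarray(AGE_GROUPS)[age_idx],
            "entry_date": start,
            "exit_date": start + pd.to_timedelta(exit_days, unit="D"),
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "is_incident_tbi": incident,
            "incident_membership_prob": member_p,
            "index_date": pd.Series(
                np.where(incident, index_day, np.nan), dtype=float
            ).map(lambda d: start + pd.Timedelta(days=d) if d == d else pd.NaT),
            "severity": np.where(
                incident, np.where(severe, SEVERITIES[1], SEVERITIES[0]), None
            ),
            "has_recurrence": has_rec,
            "recurrence_day": pd.array(
                np.where(has_rec, rec_day, -1), dtype="Int64"
            ),
        }
    )
    truth.loc[~has_rec, "recurrence_day"] = pd.NA
    return patients, truth


def _noise_day_weights(decay: float) -> np.ndarray:
    """Geometric weights over days 7..30 for early follow-up noise."""
    d = np.arange(7, 31)
    w = decay ** (d - 7)
    return w / w.sum()


def emit_claims(
    patients: pd.DataFrame, truths: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Generate the administrative claim stream implied by the latent truth.

    Conditional on the latent recurrence class, the four definitions are
    independent, matching the latent class model's assumption:

    * a true recurrence at day ``d`` produces definition ``j``'s
      qualifying claim-set at day ``d`` with probability ``se[j]``;
    * a non-recurrent index patient produces a false qualifying claim-set
      for definition ``j`` with total probability ``1 - sp[j]``, dated
      either in the early follow-up period (days 7-30, geometric decay)
      or uniformly over days 7-365.  The early share is
      ``min(1, E_j / (1 - sp[j]))`` where ``E_j = followup_noise_rate *
      sum(decay^(d-7))`` is the expected early-noise count, so the
      marginal specificity always equals ``sp[j]`` while a larger noise
      rate concentrates the false-positive mass earlier.

    The radiology definition's claim-set is an imaging billing claim plus
    a trauma-coded physician claim dated 0-1 days later. Every incident
    patient also receives index-event claims at day 0 (an ER TBI claim;
    plus a DAD entry for the most severe), which the ascertainment window
    attributes to the index episode. Claims after cohort exit are never
    emitted.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    start = pd.Timestamp(config.study_window[0])

    df = truths.merge(patients[["patient_id", "exit_date"]], on="patient_id")
    df = df[df["is_incident_tbi"]].reset_index(drop=True)
    index_day = (pd.to_datetime(df["index_date"]) - start).dt.days.to_numpy()
    exit_day = (pd.to_datetime(df["exit_date"]) - start).dt.days.to_numpy()
    exit_rel = exit_day - index_day
    n = len(df)
    se = np.asarray(config.se_by_definition)
    sp = np.asarray(config.sp_by_definition)

    rows_pid: list[np.ndarray] = []
    rows_day: list[np.ndarray] = []
    rows_src: list[np.ndarray] = []
    rows_code: list[np.ndarray] = []
    rows_sys: list[np.ndarray] = []

    def emit(pid, day, source, code, system):
        rows_pid.append(np.asarray(pid))
        rows_day.append(np.asarray(day))
        k = len(rows_pid[-1])
        rows_src.append(np.full(k, source))
        rows_code.append(np.asarray(code) if np.ndim(code) else np.full(k, code))
        rows_sys.append(np.asarray(system) if np.ndim(system) else np.full(k, system))

    pid = df["patient_id"].to_numpy()

    # --- index-event claims (day 0) -------------------------------------
    emit(pid, index_day, "emergency",
         rng.choice(_ICD9_TBI_CODES, size=n), "ICD9")
    sev = (df["severity"] == SEVERITIES[1]).to_numpy()
    if sev.any():
        _emit_dad(emit, rng, pid[sev], index_day[sev], start)

    # --- true-recurrence claim-sets -------------------------------------
    rec = df["has_recurrence"].to_numpy(dtype=bool)
    rec_day = df["recurrence_day"].fillna(0).to_numpy(dtype=int)
    observable = rec & (rec_day <= exit_rel)
    for j, name in enumerate(DEFINITIONS):
        fires = observable & (rng.random(n) < se[j])
        if not fires.any():
            continue
        day_abs = index_day[fires] + rec_day[fires]
        _emit_definition_claims(emit, rng, name, pid[fires], day_abs,
                                exit_day[fires], start)

    # hospital physician claims around severe recurrences: parsed by the
    # pipeline but used by no definition (index-hospitalisation care)
    hosp = observable & sev & (rng.random(n) < 0.3)
    if hosp.any():
        emit(pid[hosp], index_day[hosp] + rec_day[hosp], "hospital_physician",
             rng.choice(_ICD9_TBI_CODES, size=int(hosp.sum())), "ICD9")

    # --- false-positive claim-sets on non-recurrent follow-up ------------
    noise_w = _noise_day_weights(config.followup_noise_decay)
    expected_early = config.followup_noise_rate * (
        (1.0 - config.followup_noise_decay ** 24) / (1.0 - config.followup_noise_decay)
        if config.followup_noise_decay < 1.0 else 24.0
    )
    nonrec = ~rec
    for j, name in enumerate(DEFINITIONS):
        fp_prob = 1.0 - sp[j]
        if fp_prob <= 0.0:
            continue
        fp = nonrec & (rng.random(n) < fp_prob)
        if not fp.any():
            continue
        m = int(fp.sum())
        early_share = min(1.0, expected_early / fp_prob)
        early = rng.random(m) < early_share
        day_rel = np.where(
            early,
            rng.choice(np.arange(7, 31), size=m, p=noise_w),
            rng.integers(7, 366, size=m),
        )
        keep = day_rel <= exit_rel[fp]
        if not keep.any():
            continue
        _emit_definition_claims(
            emit, rng, name, pid[fp][keep], index_day[fp][keep] + day_rel[keep],
            exit_day[fp][keep], start,
        )

    claims = pd.DataFrame(
        {
            "patient_id": np.concatenate(rows_pid),
            "service_date": start
            + pd.to_timedelta(np.concatenate(rows_day), unit="D"),
            "source": np.concatenate(rows_src),
            "code": np.concatenate(rows_code),
            "code_system": np.concatenate(rows_sys),
        }
    )
    return claims.sort_values(["patient_id", "service_date"], kind="stable").reset_index(
        drop=True
    )


def _emit_dad(emit, rng, pid, day_abs, start):
    """DAD entries use ICD-9 up to 2006 and ICD-10 from 2007 on."""
    year = (start + pd.Timedelta(days=0)).year + day_abs // 365  # approximate
    icd10 = year >= _DAD_ICD10_FROM_YEAR
    codes = np.where(
        icd10,
        rng.choice(_ICD10_TBI_CODES, size=len(pid)),
        rng.choice(_ICD9_TBI_CODES, size=len(pid)),
    )
    systems = np.where(icd10, "ICD10", "ICD9")
    emit(pid, day_abs, "dad", codes, systems)


def _emit_definition_claims(emit, rng, name, pid, day_abs, exit_abs, start):
    """Emit the qualifying claim-set for one definition at given days."""
    k = len(pid)
    if name == "outpatient":
        emit(pid, day_abs, "outpatient", rng.choice(_ICD9_TBI_CODES, size=k), "ICD9")
    elif name == "er":
        emit(pid, day_abs, "emergency", rng.choice(_ICD9_TBI_CODES, size=k), "ICD9")
    elif name == "dad":
        _emit_dad(emit, rng, pid, day_abs, start)
    elif name == "radiology":
        emit(pid, day_abs, "radiology_billing",
             rng.choice(_RADIOLOGY_CODES, size=k), "billing")
        # paired trauma physician claim, same day or the next (never past exit)
        offset = rng.integers(0, 2, size=k)
        trauma_day = np.minimum(day_abs + offset, exit_abs)
        emit(pid, trauma_day, "outpatient", rng.choice(_TRAUMA_CODES, size=k), "ICD9")
    else:  # pragma: no cover - guarded by DEFINITIONS
        raise ArgumentError(f"unknown definition {name!r}")


def draw_incident_cohorts(
    truths: pd.DataFrame, n_cohorts: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Draw predicted index-TBI cohorts from the membership probabilities.

    Each cohort includes patient ``i`` independently with probability
    ``incident_membership_prob[i]``, reproducing the mechanism by which
    the upstream incident-TBI model's uncertainty propagates into the
    recurrence analysis. Returns a boolean (n_cohorts, n_patients) matrix
    aligned with the row order of ``truths``; the default of 1,000 cohorts
    matches the predicted-cohort design of the motivating analysis.
    """
    if n_cohorts < 1:
        raise ArgumentError(f"n_cohorts must be >= 1, got {n_cohorts}")
    probs = truths["incident_membership_prob"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    return rng.random((n_cohorts, len(probs))) < probs[None, :]


def write_simulation(
    out_dir: str | Path,
    patients: pd.DataFrame,
    truths: pd.DataFrame,
    claims: pd.DataFrame,
    config: SimConfig,
) -> dict:
    """Write the three tables as CSV plus a JSON metadata file (seed included)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients.to_csv(out / "patients.csv", index=False)
    truths.to_csv(out / "truth.csv", index=False)
    claims.to_csv(out / "claims.csv", index=False)
    meta = {"config": asdict(config), "seed": config.seed,
            "n_patients": len(patients), "n_claims": len(claims)}
    (out / "simulation_meta.json").write_text(json.dumps(meta, indent=2))
    return meta
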