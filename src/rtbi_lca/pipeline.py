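"""End-to-end orchestration: simulate -> ascertain -> fit -> check -> pool
-> report.

The pipeline mirrors the full surveillance analysis on synthetic data:
for each age stratum it draws M predicted index-TBI cohorts from the
membership probabilities, refits the two-class latent class model per
cohort (with the sex covariate on latent prevalence), pools posterior
draws within stratum, checks fit by posterior predictive pairwise
agreement, pools across strata weighted by mean predicted cohort size,
and writes report tables shaped like the crude-summary, incidence, and
definition-accuracy tables of a surveillance study, plus a run manifest
with every seed used.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blcm import MCMCSettings, PosteriorDraws
from .case_ascertainment import (
    DEFINITIONS,
    AscertainmentWindow,
    ResponsePatternCounts,
    apply_case_definitions,
    build_response_patterns,
    compute_person_time,
    crude_incidence,
    crude_median_time,
    pattern_matrix,
)
from .derived_estimates import adjusted_median_time, npv, ppv
from .errors import ConfigurationError, PipelineError, ValidationError
from .model_checking import posterior_predictive_check
from .pooling import (
    StratumWeights,
    pool_across_strata,
    pool_draws,
    run_multi_cohort,
    summarize,
)
from .synthetic_cohort import (
    AGE_GROUPS,
    SimConfig,
    draw_incident_cohorts,
    emit_claims,
    simulate_population,
    write_simulation,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_claims_file"]


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults for a full synthetic run.

    The production-scale design is 1,000 predicted cohorts and
    3 x 20,000 MCMC iterations per fit; the desk default (50 cohorts,
    2 x 3,000 iterations) keeps an end-to-end run in minutes while
    exercising every stage at full fidelity.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_cohorts: int = 50
    min_day: int = 7
    max_day: int = 365
    n_chains: int = 2
    n_iterations: int = 3_000
    burn_in: int = 1_000
    draw_budget: int = 200
    ppc_reps: int = 200
    ppc_cohorts: int = 5
    use_sex_covariate: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", {})
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_raw) - sim_fields
        if bad:
            raise ConfigurationError(f"unknown sim config fields: {sorted(bad)}")
        top_fields = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        bad = set(raw) - top_fields
        if bad:
            raise ConfigurationError(f"unknown config fields: {sorted(bad)}")

        def tuplify(v):
            return tuple(tuplify(x) for x in v) if isinstance(v, list) else v

        sim = SimConfig(**{k: tuplify(v) for k, v in sim_raw.items()})
        return cls(sim=sim, **raw)

    def apply_overrides(self, overrides: dict | None) -> "PipelineConfig":
        """Apply flat overrides; ``sim.``-prefixed keys reach the generator."""
        if not overrides:
            return self
        top = {k: v for k, v in overrides.items()
               if v is not None and not k.startswith("sim.")}
        sim_over = {k[4:]: v for k, v in overrides.items()
                    if v is not None and k.startswith("sim.")}
        cfg = dataclasses.replace(self, **top) if top else self
        if sim_over:
            cfg = dataclasses.replace(cfg, sim=dataclasses.replace(cfg.sim, **sim_over))
        return cfg

    @property
    def window(self) -> AscertainmentWindow:
        return AscertainmentWindow(self.min_day, self.max_day)

    def mcmc(self, seed: int) -> MCMCSettings:
        return MCMCSettings(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            seed=seed,
        )


@dataclass
class RunManifest:
    """What a run did: config snapshot, seeds, stage status, outputs."""

    config: dict
    master_seed: int
    version: str
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def record(self, stage: str, status: str, seconds: float, **extra) -> None:
        self.stages[stage] = {"status": status, "seconds": round(seconds, 3), **extra}

    def write(self, out_dir: Path) -> Path:
        missing = [f for f in self.outputs if not (out_dir / f).exists()]
        if missing:
            raise PipelineError(f"manifest lists missing outputs: {missing}")
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic fan-out of the master seed, one stream per stage
    (CRC32 of the stage name keeps it stable across processes)."""
    h = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def _pooled_as_draws(pool: dict[str, np.ndarray], settings: MCMCSettings) -> PosteriorDraws:
    """Wrap a pooled mixture of posteriors as a draws object for the
    derived-estimate helpers. Convergence was assessed per cohort, so no
    R-hat is attached here."""
    names = list(pool)
    arr = np.stack([pool[n] for n in names], axis=1)[None, :, :]
    return PosteriorDraws(
        names=names, draws=arr, rhat={}, settings=settings,
        warnings=["pooled draws: convergence assessed per cohort fit"],
    )


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    overrides: dict | None = None,
) -> RunManifest:
    """Run the full synthetic surveillance analysis and write all reports.

    Returns the :class:`RunManifest`; raises :class:`PipelineError` on a
    fatal stage failure (recorded in the manifest on disk as well).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    config = config.apply_overrides(overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.seed
    sim_cfg = dataclasses.replace(config.sim, seed=_stage_seed(master, "simulate"))
    manifest = RunManifest(
        config=dataclasses.asdict(dataclasses.replace(config, sim=sim_cfg)),
        master_seed=master,
        version=__version__,
    )

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    patients, truth = simulate_population(sim_cfg)
    claims = emit_claims(patients, truth, sim_cfg)
    write_simulation(out, patients, truth, claims, sim_cfg)
    manifest.record("simulate", "ok", time.perf_counter() - t0,
                    n_patients=len(patients), n_claims=len(claims))
    manifest.outputs += ["patients.csv", "truth.csv", "claims.csv",
                         "simulation_meta.json"]

    # --- ascertain ------------------------------------------------------
    t0 = time.perf_counter()
    incident = truth[truth["is_incident_tbi"]].reset_index(drop=True)
    index_episodes = incident[["patient_id", "index_date"]]
    hits = apply_case_definitions(claims, index_episodes, window=config.window)
    hits = hits.merge(
        patients[["patient_id", "age_group", "sex", "exit_date"]], on="patient_id"
    )
    hits = hits.merge(
        incident[["patient_id", "index_date", "incident_membership_prob"]],
        on="patient_id",
    )
    hits.to_csv(out / "hits.csv", index=False)
    crude_rows = []
    for age in AGE_GROUPS:
        sub = hits[hits["age_group"] == age]
        sub_idx = index_episodes[index_episodes["patient_id"].isin(sub["patient_id"])]
        _, total_py = compute_person_time(
            sub_idx, sub, patients, window=config.window
        )
        n_cases = int(sub[list(DEFINITIONS)].any(axis=1).sum())
        crude_rows.append(
            {
                "age_group": age,
                "suspected_incident_n": len(sub),
                "suspected_recurrent_n": n_cases,
                "person_years": total_py,
                "crude_incidence_per_100py": crude_incidence(n_cases, total_py),
                "crude_median_days": (
                    crude_median_time(sub) if n_cases else np.nan
                ),
            }
        )
    crude = pd.DataFrame(crude_rows)
    manifest.record("ascertain", "ok", time.perf_counter() - t0,
                    n_suspected=int(crude["suspected_recurrent_n"].sum()))

    # --- fit: M predicted cohorts per stratum ---------------------------
    t0 = time.perf_counter()
    flags_all = hits[list(DEFINITIONS)].to_numpy(dtype=bool)
    male_all = (hits["sex"] == "M").to_numpy()
    stratum_pools: dict[str, dict[str, np.ndarray]] = {}
    per_cohort_records = []
    mean_cohort_sizes: dict[str, float] = {}
    ppc_material: dict[str, list] = {}
    for age in AGE_GROUPS:
        age_mask = (hits["age_group"] == age).to_numpy()
        age_truth = incident[incident["patient_id"].isin(
            hits.loc[age_mask, "patient_id"])]
        cohorts_bool = draw_incident_cohorts(
            age_truth, config.n_cohorts, seed=_stage_seed(master, f"cohorts-{age}")
        )
        age_flags = flags_all[age_mask]
        age_male = male_all[age_mask]
        cohorts = []
        for m in range(config.n_cohorts):
            members = cohorts_bool[m]
            if config.use_sex_covariate:
                cohorts.append((age_flags[members], age_male[members]))
            else:
                cohorts.append(
                    ResponsePatternCounts.from_flags(age_flags[members])
                )
        mean_cohort_sizes[age] = float(cohorts_bool.sum(axis=1).mean())
        results = run_multi_cohort(
            cohorts, fit_settings=config.mcmc(_stage_seed(master, f"fit-{age}"))
        )
        per_cohort_records += [
            {"age_group": age, "cohort": r.cohort_index, "status": r.status,
             "seed": r.seed, "error": r.error,
             "converged": bool(r.draws.converged) if r.draws else None}
            for r in results
        ]
        stratum_pools[age] = pool_draws(results, config.draw_budget)
        ok = [r for r in results if r.status == "ok"]
        ppc_material[age] = [
            (r.draws, ResponsePatternCounts.from_flags(age_flags[cohorts_bool[r.cohort_index]]))
            for r in ok[: config.ppc_cohorts]
        ]
        pd.DataFrame(
            {n: v for n, v in stratum_pools[age].items()}
        ).to_csv(out / f"pooled_draws_{age}.csv", index=False)
        manifest.outputs.append(f"pooled_draws_{age}.csv")
    pd.DataFrame(per_cohort_records).to_csv(out / "cohort_fits.csv", index=False)
    manifest.outputs.append("cohort_fits.csv")
    n_failed = sum(r["status"] != "ok" for r in per_cohort_records)
    manifest.record("fit", "ok", time.perf_counter() - t0,
                    cohorts_per_stratum=config.n_cohorts, failed_fits=n_failed)

    # --- check: per-cohort PPC, median p per pair -----------------------
    t0 = time.perf_counter()
    ppc_rows = []
    for age in AGE_GROUPS:
        per_pair: dict[tuple[int, int], list] = {}
        observed: dict[tuple[int, int], float] = {}
        for k, (draws, counts) in enumerate(ppc_material[age]):
            for res in posterior_predictive_check(
                draws, counts, n_reps=config.ppc_reps,
                seed=_stage_seed(master, f"ppc-{age}-{k}"),
            ):
                per_pair.setdefault(res.pair, []).append(res.bayesian_p)
                observed[res.pair] = res.observed_agreement
        for pair, ps in per_pair.items():
            p = float(np.median(ps))
            ppc_rows.append(
                {
                    "age_group": age,
                    "pair": f"{DEFINITIONS[pair[0]]}-{DEFINITIONS[pair[1]]}",
                    "observed_agreement": observed[pair],
                    "bayesian_p": p,
                    "flagged": not (0.05 < p < 0.95),
                }
            )
    ppc_table = pd.DataFrame(ppc_rows)
    ppc_table.to_csv(out / "ppc.csv", index=False)
    manifest.outputs.append("ppc.csv")
    manifest.record("check", "ok", time.perf_counter() - t0,
                    flagged_pairs=int(ppc_table["flagged"].sum()) if len(ppc_table) else 0)

    # --- pool across strata ---------------------------------------------
    t0 = time.perf_counter()
    weights = StratumWeights.from_cohort_sizes(mean_cohort_sizes)
    overall = pool_across_strata(
        stratum_pools, weights, seed=_stage_seed(master, "pool")
    )
    pd.DataFrame(overall).to_csv(out / "pooled_draws_overall.csv", index=False)
    manifest.outputs.append("pooled_draws_overall.csv")
    manifest.record("pool", "ok", time.perf_counter() - t0,
                    weights={a: round(float(w), 4)
                             for a, w in zip(weights.labels, weights.weights)})

    # --- report ---------------------------------------------------------
    t0 = time.perf_counter()
    _write_reports(out, config, crude, hits, stratum_pools, overall, manifest)
    manifest.record("report", "ok", time.perf_counter() - t0)
    manifest.write(out)
    manifest.outputs.append("manifest.json")
    return manifest


def _write_reports(out, config, crude, hits, stratum_pools, overall, manifest):
    pools = dict(stratum_pools)
    pools["overall"] = overall

    # incidence table (per stratum and overall, per 100 person-years)
    inc_rows = []
    for label, pool in pools.items():
        est = summarize(pool["pi"] * 100.0, name="adjusted_incidence")
        row = {
            "stratum": label,
            "adjusted_incidence_per_100py": est.median,
            "hdi_low": est.hdi_low,
            "hdi_high": est.hdi_high,
        }
        if "beta_sex" in pool:
            or_est = summarize(np.exp(pool["beta_sex"]), name="male_female_or")
            row.update(
                male_female_or=or_est.median,
                male_female_or_low=or_est.hdi_low,
                male_female_or_high=or_est.hdi_high,
            )
        inc_rows.append(row)
    pd.DataFrame(inc_rows).to_csv(out / "table_incidence.csv", index=False)

    # accuracy table: Se, Sp, and draw-wise PPV/NPV per definition
    acc_rows = []
    for label, pool in pools.items():
        pi = pool["pi"]
        for d in DEFINITIONS:
            se, sp = pool[f"se_{d}"], pool[f"sp_{d}"]
            for qname, arr in (
                ("se", se),
                ("sp", sp),
                ("ppv", ppv(pi, se, sp)),
                ("npv", npv(pi, se, sp)),
            ):
                est = summarize(arr, name=qname)
                acc_rows.append(
                    {
                        "stratum": label,
                        "definition": d,
                        "quantity": qname,
                        "median": est.median,
                        "hdi_low": est.hdi_low,
                        "hdi_high": est.hdi_high,
                    }
                )
    pd.DataFrame(acc_rows).to_csv(out / "table_accuracy.csv", index=False)

    # crude table + adjusted median time per stratum
    adj_rows = []
    y_bits = 2 ** np.arange(len(DEFINITIONS) - 1, -1, -1)
    for age, pool in stratum_pools.items():
        sub = hits[(hits["age_group"] == age)
                   & hits[list(DEFINITIONS)].any(axis=1)]
        if len(sub) == 0:
            adj_rows.append({"age_group": age, "adjusted_median_days": np.nan,
                             "hdi_low": np.nan, "hdi_high": np.nan})
            continue
        days = sub["first_hit_day"].to_numpy(dtype=float)
        patterns = (sub[list(DEFINITIONS)].to_numpy(dtype=int) @ y_bits)
        est = adjusted_median_time(
            days,
            patterns=patterns,
            incident_probs=sub["incident_membership_prob"].to_numpy(dtype=float),
            draws=_pooled_as_draws(pool, config.mcmc(0)),
        )
        adj_rows.append(
            {"age_group": age, "adjusted_median_days": est.median,
             "hdi_low": est.hdi_low, "hdi_high": est.hdi_high}
        )
    crude_table = crude.merge(pd.DataFrame(adj_rows), on="age_group")
    crude_table.to_csv(out / "table_crude.csv", index=False)
    manifest.outputs += ["table_incidence.csv", "table_accuracy.csv",
                         "table_crude.csv", "hits.csv"]


# ---------------------------------------------------------------------------
# claims-file validation
# ---------------------------------------------------------------------------

@dataclass
class ClaimsValidationReport:
    """Row counts, schema errors with line numbers, and the date range."""

    path: str
    n_rows: int
    errors: list
    date_min: str | None
    date_max: str | None

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_claims_file(path: str | Path) -> ClaimsValidationReport:
    """Validate a claims CSV: schema, enumerations, parseable dates.

    Error entries are ``(line_number, message)`` with line numbers
    matching the file (header is line 1).
    """
    from .case_ascertainment import CLAIM_SOURCES, CODE_SYSTEMS

    path = Path(path)
    try:
        claims = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: no records") from exc
    except OSError as exc:
        raise ValidationError(f"{path}: unreadable ({exc})") from exc
    required = ["patient_id", "service_date", "source", "code", "code_system"]
    errors: list[tuple[int, str]] = []
    missing = [c for c in required if c not in claims.columns]
    if missing:
        errors.append((1, f"missing columns: {missing}"))
        return ClaimsValidationReport(str(path), len(claims), errors, None, None)
    if len(claims) == 0:
        raise ValidationError(f"{path}: no records")
    dates = pd.to_datetime(claims["service_date"], errors="coerce")
    for idx in claims.index[dates.isna()]:
        errors.append((int(idx) + 2, "unparseable service_date"))
    for idx in claims.index[~claims["source"].isin(CLAIM_SOURCES)]:
        errors.append((int(idx) + 2, f"unknown source {claims.at[idx, 'source']!r}"))
    for idx in claims.index[~claims["code_system"].isin(CODE_SYSTEMS)]:
        errors.append(
            (int(idx) + 2, f"unknown code_system {claims.at[idx, 'code_system']!r}")
        )
    valid = dates.dropna()
    return ClaimsValidationReport(
        str(path),
        len(claims),
        sorted(errors),
        str(valid.min().date()) if len(valid) else None,
        str(valid.max().date()) if len(valid) else None,
    )
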