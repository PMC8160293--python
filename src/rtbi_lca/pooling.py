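"""Uncertainty propagation across predicted cohorts, and posterior pooling.

The upstream incident-TBI model yields a posterior over who truly had an
index TBI. That uncertainty is carried into the recurrence analysis by
refitting the latent class model on M predicted cohorts (each a Bernoulli
draw from the membership probabilities) and pooling equal budgets of
post-burn-in draws across the M fits — the multiple-imputation-style
mixture of posteriors. Age strata are then combined by resampling each
stratum's pool in proportion to its mean predicted cohort size.

Summaries are posterior medians with 95% highest-density intervals
computed by the shortest-contiguous-interval estimator on sorted draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blcm import LCMPriors, MCMCSettings, PosteriorDraws, fit_two_class
from .errors import (
    ArgumentError,
    EmptyInputError,
    PipelineError,
    SchemaError,
)

__all__ = [
    "PooledEstimate",
    "StratumWeights",
    "CohortFitResult",
    "run_multi_cohort",
    "pool_draws",
    "pool_across_strata",
    "hdi",
    "summarize",
]


@dataclass(frozen=True)
class PooledEstimate:
    """Median and 95% HDI of one scalar after pooling."""

    name: str
    median: float
    hdi_low: float
    hdi_high: float
    n_draws: int

    def __post_init__(self) -> None:
        if not (self.hdi_low <= self.median <= self.hdi_high):
            raise ArgumentError(
                f"{self.name}: HDI ({self.hdi_low}, {self.hdi_high}) does not "
                f"bracket the median {self.median}"
            )


@dataclass
class StratumWeights:
    """Normalized pooling weights, proportional to index-cohort sizes."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.labels):
            raise ArgumentError("labels and weights must have equal length")
        if (w < 0).any():
            raise ArgumentError("weights must be non-negative")
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ArgumentError("weights must have a positive finite sum")
        self.weights = w / total

    @classmethod
    def from_cohort_sizes(cls, sizes: dict[str, float]) -> "StratumWeights":
        return cls(tuple(sizes), np.asarray(list(sizes.values()), dtype=float))


@dataclass
class CohortFitResult:
    """Outcome of fitting one predicted cohort (failures are recorded,
    not fatal)."""

    cohort_index: int
    status: str  # "ok" | "failed"
    draws: PosteriorDraws | None = None
    error: str | None = None
    seed: int | None = None


def _child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-cohort seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_multi_cohort(
    cohorts,
    fit_settings: MCMCSettings,
    priors: LCMPriors | None = None,
) -> list[CohortFitResult]:
    """Fit the two-class model once per predicted cohort.

    ``cohorts`` is a sequence whose elements are either pattern counts
    (anything :func:`fit_two_class` accepts) or ``(flags, male)`` tuples
    when the sex covariate is active. Cohort-specific seeds are derived
    deterministically from ``fit_settings.seed``; a failed fit is
    recorded in its :class:`CohortFitResult` and does not abort the run.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise EmptyInputError("no cohorts supplied")
    results: list[CohortFitResult] = []
    for i, cohort in enumerate(cohorts):
        seed = _child_seed(fit_settings.seed, i)
        settings = MCMCSettings(
            n_chains=fit_settings.n_chains,
            n_iterations=fit_settings.n_iterations,
            burn_in=fit_settings.burn_in,
            thin=fit_settings.thin,
            seed=seed,
        )
        try:
            if isinstance(cohort, tuple) and len(cohort) == 2:
                draws = fit_two_class(
                    cohort[0], covariate_male=cohort[1], priors=priors,
                    settings=settings,
                )
            else:
                draws = fit_two_class(cohort, priors=priors, settings=settings)
            results.append(
                CohortFitResult(i, "ok", draws=draws, seed=seed)
            )
        except Exception as exc:  # noqa: BLE001 - per-cohort isolation
            results.append(
                CohortFitResult(i, "failed", error=str(exc), seed=seed)
            )
    if all(r.status == "failed" for r in results):
        detail = "; ".join(f"cohort {r.cohort_index}: {r.error}" for r in results[:5])
        raise PipelineError(f"every cohort fit failed ({detail})")
    return results


def pool_draws(
    fits: list[CohortFitResult] | list[PosteriorDraws],
    per_cohort_draw_budget: int,
) -> dict[str, np.ndarray]:
    """Thin each cohort's post-burn-in draws to an equal budget and
    concatenate into a mixture-of-posteriors pool.

    Returns ``{parameter: pooled array}`` with each array of length
    (number of successful cohorts) x budget.
    """
    if per_cohort_draw_budget < 1:
        raise ArgumentError("per_cohort_draw_budget must be >= 1")
    draws_list = [
        f.draws if isinstance(f, CohortFitResult) else f
        for f in fits
        if not (isinstance(f, CohortFitResult) and f.status != "ok")
    ]
    if not draws_list:
        raise EmptyInputError("no successful fits to pool")
    names = draws_list[0].names
    for d in draws_list[1:]:
        if d.names != names:
            raise SchemaError(
                f"parameter sets differ across cohorts: {d.names} vs {names}"
            )
    pooled: dict[str, list[np.ndarray]] = {n: [] for n in names}
    for d in draws_list:
        flat = d.draws.reshape(-1, len(names))
        if len(flat) < per_cohort_draw_budget:
            raise ArgumentError(
                f"budget {per_cohort_draw_budget} exceeds the {len(flat)} "
                "available post-burn-in draws"
            )
        idx = np.linspace(0, len(flat) - 1, per_cohort_draw_budget).astype(int)
        for k, n in enumerate(names):
            pooled[n].append(flat[idx, k])
    return {n: np.concatenate(v) for n, v in pooled.items()}


def pool_across_strata(
    stratum_pools: dict[str, dict[str, np.ndarray] | np.ndarray],
    weights: StratumWeights,
    seed: int = 0,
) -> dict[str, np.ndarray] | np.ndarray:
    """Combine per-stratum pools into an overall mixture of posteriors.

    Draws are resampled (with replacement) from each stratum in
    proportion to its weight; the overall pool is size-matched to the
    largest stratum pool. Accepts either plain arrays per stratum or
    ``{parameter: array}`` dicts (resampled jointly per stratum so
    cross-parameter dependence within a draw is preserved).
    """
    if set(stratum_pools) != set(weights.labels):
        raise ArgumentError(
            f"stratum labels {sorted(stratum_pools)} do not match weight "
            f"labels {sorted(weights.labels)}"
        )
    rng = np.random.default_rng(seed)
    first = next(iter(stratum_pools.values()))
    dict_mode = isinstance(first, dict)

    def pool_len(p):
        return len(next(iter(p.values()))) if isinstance(p, dict) else len(p)

    size = max(pool_len(p) for p in stratum_pools.values())
    counts = rng.multinomial(size, weights.weights)
    if dict_mode:
        out: dict[str, list[np.ndarray]] = {}
        for label, m in zip(weights.labels, counts):
            pool = stratum_pools[label]
            idx = rng.integers(0, pool_len(pool), size=m)
            for name, arr in pool.items():
                out.setdefault(name, []).append(np.asarray(arr)[idx])
        return {n: np.concatenate(v) for n, v in out.items()}
    parts = []
    for label, m in zip(weights.labels, counts):
        arr = np.asarray(stratum_pools[label])
        idx = rng.integers(0, len(arr), size=m)
        parts.append(arr[idx])
    return np.concatenate(parts)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise EmptyInputError("no draws supplied")
    k = max(int(np.ceil(mass * n)), 1)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize(draws: np.ndarray, name: str = "parameter") -> PooledEstimate:
    """Posterior median and 95% HDI of a pooled draw array."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise EmptyInputError("no draws supplied")
    if x.size < 100:
        warnings.warn(
            f"{name}: only {x.size} draws; interval estimates will be coarse",
            UserWarning,
            stacklevel=2,
        )
    lo, hi = hdi(x)
    med = float(np.median(x))
    # a point-mass pool can place the median at an HDI endpoint exactly
    med = min(max(med, lo), hi)
    return PooledEstimate(name, med, lo, hi, int(x.size))


def summaries_frame(pool: dict[str, np.ndarray]) -> pd.DataFrame:
    """Summarize every parameter in a pool into a tidy frame."""
    rows = [summarize(arr, name) for name, arr in pool.items()]
    return pd.DataFrame(
        {
            "parameter": [r.name for r in rows],
            "median": [r.median for r in rows],
            "hdi_low": [r.hdi_low for r in rows],
            "hdi_high": [r.hdi_high for r in rows],
            "n_draws": [r.n_draws for r in rows],
        }
    )
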