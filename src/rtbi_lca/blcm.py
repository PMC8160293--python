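"""Two-class Bayesian latent class model for imperfect case definitions.

The model: each subject belongs to a latent class C (1 = true recurrent
case, 0 = not) with prevalence pi; given C, the four binary case
definitions are conditionally independent, definition j firing with
probability Se_j when C = 1 and 1 - Sp_j when C = 0. The 16 response
patterns are therefore multinomial with cell probabilities

    P(y) = pi * prod_j Se_j^y_j (1-Se_j)^(1-y_j)
         + (1-pi) * prod_j (1-Sp_j)^y_j Sp_j^(1-y_j).

Priors are truncated Beta distributions; the truncation ranges act as the
"non-informative constraints" that stabilise the fit across many sparse
predicted cohorts and, together with a joint Se_j + Sp_j > 1 guard on the
constrained definitions, prevent label switching.

Estimation is Gibbs sampling with latent-class data augmentation: the
latent split of each pattern's count is Binomial given the current
parameters, and pi, Se_j, Sp_j then have conjugate truncated-Beta full
conditionals. An optional logistic layer replaces pi with
logit^-1(beta0 + beta_sex * male_i); (beta0, beta_sex) are updated with an
adaptive random-walk Metropolis step (adaptation during burn-in only).

A brute-force grid posterior over small instances serves as an
independent check of the sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betainc, betaincinv, betaln, expit, logit, logsumexp
from scipy.stats import beta as beta_dist

from .case_ascertainment import DEFINITIONS, ResponsePatternCounts, pattern_matrix
from .errors import (
    ArgumentError,
    DegenerateInputError,
    EmptyInputError,
    GridSizeError,
    SchemaError,
)

__all__ = [
    "LCMParams",
    "BetaPrior",
    "LCMPriors",
    "MCMCSettings",
    "PosteriorDraws",
    "pattern_likelihood",
    "pattern_probabilities",
    "fit_two_class",
    "brute_force_posterior",
    "gelman_rubin",
]

_RHAT_THRESHOLD = 1.1


@dataclass
class LCMParams:
    """Point values of the two-class model parameters."""

    pi: float
    se: np.ndarray
    sp: np.ndarray
    beta0: float | None = None
    beta_sex: float | None = None

    def __post_init__(self) -> None:
        self.se = np.asarray(self.se, dtype=float)
        self.sp = np.asarray(self.sp, dtype=float)
        if self.se.shape != self.sp.shape:
            raise ArgumentError("se and sp must have the same length")
        for name, v in (("pi", np.array([self.pi])), ("se", self.se), ("sp", self.sp)):
            if np.any((v <= 0.0) | (v >= 1.0)):
                raise ArgumentError(f"{name} must lie strictly inside (0, 1), got {v}")

    @property
    def n_definitions(self) -> int:
        return len(self.se)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior truncated to (lower, upper)."""

    a: float = 1.0
    b: float = 1.0
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ArgumentError(
                f"truncation range must satisfy 0 <= lower < upper <= 1, "
                f"got ({self.lower}, {self.upper})"
            )
        if self.a <= 0 or self.b <= 0:
            raise ArgumentError("Beta hyperparameters must be positive")


@dataclass(frozen=True)
class LCMPriors:
    """Priors for pi, Se_j, Sp_j plus the set of jointly constrained tests.

    The default reconstruction: prevalence Beta(1,1) truncated to
    (0, 0.25); all specificities truncated to (0.7, 1); the ER and DAD
    sensitivities truncated to (0.02, 0.9); remaining sensitivities flat
    on (0, 1). ``joint_constrained`` lists the definition indices on which
    a drawn (Se_j, Sp_j) pair with Se_j + Sp_j <= 1 is rejected, which
    pins the labelling of the two classes.
    """

    pi: BetaPrior = BetaPrior(upper=0.25)
    se: tuple[BetaPrior, ...] = (
        BetaPrior(),
        BetaPrior(lower=0.02, upper=0.9),
        BetaPrior(lower=0.02, upper=0.9),
        BetaPrior(),
    )
    sp: tuple[BetaPrior, ...] = (
        BetaPrior(lower=0.7),
        BetaPrior(lower=0.7),
        BetaPrior(lower=0.7),
        BetaPrior(lower=0.7),
    )
    joint_constrained: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if len(self.se) != len(self.sp):
            raise ArgumentError("se and sp prior tuples must have equal length")
        for j in self.joint_constrained:
            if not 0 <= j < len(self.se):
                raise ArgumentError(f"constrained index {j} out of range")

    @property
    def n_definitions(self) -> int:
        return len(self.se)

    @classmethod
    def default(cls, n_definitions: int = 4) -> "LCMPriors":
        if n_definitions == 4:
            return cls()
        return cls(
            se=tuple(BetaPrior() for _ in range(n_definitions)),
            sp=tuple(BetaPrior(lower=0.7) for _ in range(n_definitions)),
            joint_constrained=(),
        )

    def param_list(self) -> list[tuple[str, BetaPrior]]:
        names = _param_names(self.n_definitions)
        return list(zip(names, (self.pi, *self.se, *self.sp)))


def _def_names(j: int) -> tuple[str, ...]:
    return DEFINITIONS if j == 4 else tuple(f"def{i + 1}" for i in range(j))


def _param_names(n_definitions: int) -> list[str]:
    names = _def_names(n_definitions)
    return (
        ["pi"]
        + [f"se_{d}" for d in names]
        + [f"sp_{d}" for d in names]
    )


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration; defaults follow the three-chain, 20,000
    iteration, 5,000 burn-in design of the motivating analysis."""

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ArgumentError("burn_in must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ArgumentError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ArgumentError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC output with convergence metadata.

    ``draws`` has shape (n_chains, n_draws, n_parameters), ordered as
    ``names``. ``rhat`` maps each parameter to its Gelman-Rubin statistic;
    ``accept_rate`` is the Metropolis acceptance rate of the logistic
    layer (None for conjugate-only fits).
    """

    names: list[str]
    draws: np.ndarray
    rhat: dict[str, float]
    settings: MCMCSettings
    accept_rate: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(r < _RHAT_THRESHOLD for r in self.rhat.values())

    def get(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        try:
            k = self.names.index(name)
        except ValueError as exc:
            raise SchemaError(f"unknown parameter {name!r}") from exc
        return self.draws[:, :, k].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        c, n, p = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), n * p),
                "iteration": np.tile(np.repeat(np.arange(n), p), c),
                "parameter": np.tile(self.names, c * n),
                "value": self.draws.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def pattern_probabilities(
    pi: float | np.ndarray, se: np.ndarray, sp: np.ndarray
) -> np.ndarray:
    """Probabilities of all 2^J response patterns under the two-class model."""
    se = np.asarray(se, dtype=float)
    sp = np.asarray(sp, dtype=float)
    y = pattern_matrix(len(se))
    p1 = np.prod(np.where(y == 1, se, 1.0 - se), axis=1)
    p0 = np.prod(np.where(y == 1, 1.0 - sp, sp), axis=1)
    return pi * p1 + (1.0 - pi) * p0


def pattern_likelihood(params: LCMParams, pattern) -> float:
    """P(y = pattern) under the two-class conditional-independence model."""
    y = np.asarray(pattern, dtype=int)
    if y.shape != params.se.shape:
        raise ArgumentError("pattern length must match the number of definitions")
    p1 = float(np.prod(np.where(y == 1, params.se, 1.0 - params.se)))
    p0 = float(np.prod(np.where(y == 1, 1.0 - params.sp, params.sp)))
    return params.pi * p1 + (1.0 - params.pi) * p0


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _sample_trunc_beta(rng, a, b, lo, hi):
    """Vectorized draws from Beta(a, b) truncated to (lo, hi) via inverse CDF."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), a.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), a.shape)
    c_lo = betainc(a, b, lo)
    c_hi = betainc(a, b, hi)
    u = c_lo + rng.random(a.shape) * (c_hi - c_lo)
    x = betaincinv(a, b, u)
    eps = 1e-12
    return np.clip(x, lo + eps, hi - eps)


def _coerce_counts(data) -> ResponsePatternCounts:
    if isinstance(data, ResponsePatternCounts):
        return data
    arr = np.asarray(data)
    if arr.ndim == 1:
        return ResponsePatternCounts(arr)
    return ResponsePatternCounts.from_flags(arr)


def fit_two_class(
    data,
    covariate_male: np.ndarray | None = None,
    priors: LCMPriors | None = None,
    settings: MCMCSettings | None = None,
) -> PosteriorDraws:
    """Fit the two-class model by Gibbs sampling.

    Parameters
    ----------
    data
        :class:`ResponsePatternCounts`, a length-2^J count vector, or an
        (n, J) boolean flag array. Aggregated counts are the sufficient
        statistic when no covariate is supplied; per-subject flags are
        required when ``covariate_male`` is given.
    covariate_male
        Optional boolean array (length n) activating the logistic layer
        logit(pi_i) = beta0 + beta_sex * male_i on latent prevalence.
    priors, settings
        Default to :meth:`LCMPriors.default` and :class:`MCMCSettings`.

    Returns
    -------
    :class:`PosteriorDraws`; non-convergence (any R-hat >= 1.1) is
    reported through ``warnings`` and a ``UserWarning``, never silently.
    """
    settings = MCMCSettings() if settings is None else settings
    if covariate_male is not None:
        flags = np.asarray(data, dtype=int)
        if flags.ndim != 2:
            raise ArgumentError(
                "per-subject flags are required when a covariate is active"
            )
        male = np.asarray(covariate_male, dtype=int)
        if len(male) != len(flags):
            raise SchemaError("covariate length must match the number of subjects")
        j = flags.shape[1]
        counts_by_sex = np.stack(
            [
                ResponsePatternCounts.from_flags(flags[male == m]).counts
                if (male == m).any()
                else np.zeros(2**j, dtype=np.int64)
                for m in (0, 1)
            ],
            axis=1,
        )  # (16, 2)
        counts = None
    else:
        counts = _coerce_counts(data)
        if counts.n == 0:
            raise EmptyInputError("pattern counts are all zero")
        j = counts.n_definitions
        counts_by_sex = None
    priors = LCMPriors.default(j) if priors is None else priors
    if priors.n_definitions != j:
        raise SchemaError(
            f"priors cover {priors.n_definitions} definitions but data has {j}"
        )

    names = _param_names(j)
    if covariate_male is not None:
        names = names + ["beta0", "beta_sex"]
    kept = (settings.n_iterations - settings.burn_in) // settings.thin
    out = np.empty((settings.n_chains, kept, len(names)))
    accept_rates = []
    child_seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    for c in range(settings.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        if covariate_male is None:
            out[c] = _run_chain_counts(rng, counts.counts, priors, settings, kept)
        else:
            out[c], acc = _run_chain_covariate(
                rng, counts_by_sex, priors, settings, kept
            )
            accept_rates.append(acc)

    rhat = {
        name: gelman_rubin(out[:, :, k]) for k, name in enumerate(names)
    }
    warn_list = []
    bad = [n for n, r in rhat.items() if not r < _RHAT_THRESHOLD]
    if bad:
        warn_list.append(
            f"possible non-convergence: R-hat >= {_RHAT_THRESHOLD} for {bad}"
        )
        warnings.warn(warn_list[-1], UserWarning, stacklevel=2)
    return PosteriorDraws(
        names=names,
        draws=out,
        rhat=rhat,
        settings=settings,
        accept_rate=float(np.mean(accept_rates)) if accept_rates else None,
        warnings=warn_list,
    )


def _init_params(rng, priors: LCMPriors):
    """Start each chain at an overdispersed point inside the truncations."""
    def draw(p: BetaPrior):
        return float(_sample_trunc_beta(rng, p.a, p.b, p.lower, p.upper))

    pi = draw(priors.pi)
    se = np.array([draw(p) for p in priors.se])
    sp = np.array([draw(p) for p in priors.sp])
    # respect the labelling constraint from the start
    for jj in priors.joint_constrained:
        while se[jj] + sp[jj] <= 1.0:
            se[jj] = draw(priors.se[jj])
            sp[jj] = draw(priors.sp[jj])
    return pi, se, sp


def _conjugate_step(rng, priors, pi, se, sp, n1_pos, n1_tot, n0_pos, n0_tot):
    """Truncated-Beta full-conditional updates with the label guard."""
    pi_p = priors.pi
    pi = float(
        _sample_trunc_beta(
            rng, pi_p.a + n1_tot, pi_p.b + n0_tot, pi_p.lower, pi_p.upper
        )
    )
    se_a = np.array([p.a for p in priors.se]) + n1_pos
    se_b = np.array([p.b for p in priors.se]) + (n1_tot - n1_pos)
    new_se = _sample_trunc_beta(
        rng, se_a, se_b,
        np.array([p.lower for p in priors.se]),
        np.array([p.upper for p in priors.se]),
    )
    sp_a = np.array([p.a for p in priors.sp]) + (n0_tot - n0_pos)
    sp_b = np.array([p.b for p in priors.sp]) + n0_pos
    new_sp = _sample_trunc_beta(
        rng, sp_a, sp_b,
        np.array([p.lower for p in priors.sp]),
        np.array([p.upper for p in priors.sp]),
    )
    # reject pair updates that would violate Se + Sp > 1 on constrained tests
    for jj in priors.joint_constrained:
        if new_se[jj] + new_sp[jj] <= 1.0:
            new_se[jj], new_sp[jj] = se[jj], sp[jj]
    return pi, new_se, new_sp


def _run_chain_counts(rng, counts, priors, settings, kept):
    j = int(np.log2(len(counts)))
    y = pattern_matrix(j)
    n_total = counts.sum()
    pi, se, sp = _init_params(rng, priors)
    out = np.empty((kept, 1 + 2 * j))
    k_out = 0
    for it in range(settings.n_iterations):
        p1 = pi * np.prod(np.where(y == 1, se, 1.0 - se), axis=1)
        p0 = (1.0 - pi) * np.prod(np.where(y == 1, 1.0 - sp, sp), axis=1)
        theta = p1 / (p1 + p0)
        n1 = rng.binomial(counts, theta)
        n1_tot = n1.sum()
        n0 = counts - n1
        pi, se, sp = _conjugate_step(
            rng, priors, pi, se, sp,
            y.T @ n1, n1_tot, y.T @ n0, n_total - n1_tot,
        )
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            out[k_out] = [pi, *se, *sp]
            k_out += 1
    return out


def _run_chain_covariate(rng, counts_by_sex, priors, settings, kept):
    """Gibbs + adaptive random-walk Metropolis for the logistic layer.

    Sufficient statistics are counts by (pattern, sex), so cost is
    independent of cohort size. Reported ``pi`` is the population-average
    prevalence at the current (beta0, beta_sex)."""
    n16, _ = counts_by_sex.shape
    j = int(np.log2(n16))
    y = pattern_matrix(j)
    n_by_sex = counts_by_sex.sum(axis=0)  # subjects per sex
    w_sex = n_by_sex / n_by_sex.sum()
    pi0, se, sp = _init_params(rng, priors)
    b = np.array([logit(pi0), 0.0])
    step = 0.2
    prior_sd = 5.0
    accepted = 0
    proposed = 0
    out = np.empty((kept, 1 + 2 * j + 2))
    k_out = 0

    def class_loglik(bvec, n1_m, n_m):
        eta = bvec[0] + bvec[1] * np.array([0.0, 1.0])
        p = expit(eta)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll = np.sum(n1_m * np.log(p) + (n_m - n1_m) * np.log1p(-p))
        return ll - np.sum(bvec**2) / (2.0 * prior_sd**2)

    for it in range(settings.n_iterations):
        pi_m = expit(b[0] + b[1] * np.array([0.0, 1.0]))  # (2,)
        a1 = np.prod(np.where(y == 1, se, 1.0 - se), axis=1)  # (16,)
        a0 = np.prod(np.where(y == 1, 1.0 - sp, sp), axis=1)
        p1 = pi_m[None, :] * a1[:, None]
        p0 = (1.0 - pi_m)[None, :] * a0[:, None]
        theta = p1 / (p1 + p0)
        n1 = rng.binomial(counts_by_sex, theta)  # (16, 2)
        n1_m = n1.sum(axis=0)
        n1_k = n1.sum(axis=1)
        n0_k = counts_by_sex.sum(axis=1) - n1_k
        _, se, sp = _conjugate_step(
            rng, priors, pi_m.mean(), se, sp,
            y.T @ n1_k, n1_k.sum(), y.T @ n0_k, n0_k.sum(),
        )
        # Metropolis update of (beta0, beta_sex) given the latent classes
        prop = b + step * rng.standard_normal(2)
        # keep the implied average prevalence inside the pi truncation
        pi_bar_prop = float(w_sex @ expit(prop[0] + prop[1] * np.array([0.0, 1.0])))
        proposed += 1
        if priors.pi.lower < pi_bar_prop < priors.pi.upper:
            logr = class_loglik(prop, n1_m, n_by_sex) - class_loglik(
                b, n1_m, n_by_sex
            )
            if np.log(rng.random()) < logr:
                b = prop
                accepted += 1
        # adapt during burn-in only
        if it < settings.burn_in and it > 0 and it % 50 == 0:
            rate = accepted / proposed
            if rate > 0.45:
                step *= 1.2
            elif rate < 0.2:
                step *= 0.8
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            pi_bar = float(w_sex @ expit(b[0] + b[1] * np.array([0.0, 1.0])))
            out[k_out] = [pi_bar, *se, *sp, b[0], b[1]]
            k_out += 1
    return out, accepted / max(proposed, 1)


# ---------------------------------------------------------------------------
# brute-force grid posterior (independent oracle for the sampler)
# ---------------------------------------------------------------------------

@dataclass
class GridPosterior:
    """Posterior evaluated on a lattice; supports marginal summaries."""

    names: list[str]
    grids: list[np.ndarray]
    posterior: np.ndarray  # normalized, shape (R,) * n_params

    def _axis(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as exc:
            raise SchemaError(f"unknown parameter {name!r}") from exc

    def marginal(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        k = self._axis(name)
        axes = tuple(i for i in range(self.posterior.ndim) if i != k)
        return self.grids[k], self.posterior.sum(axis=axes)

    def marginal_mean(self, name: str) -> float:
        g, w = self.marginal(name)
        return float(g @ w)

    def marginal_quantile(self, name: str, q: float) -> float:
        g, w = self.marginal(name)
        cdf = np.cumsum(w)
        return float(g[np.searchsorted(cdf, q)])


def brute_force_posterior(
    pattern_counts,
    grid_resolution: int,
    priors: LCMPriors | None = None,
    max_points: int = 2**24,
) -> GridPosterior:
    """Exhaustive grid evaluation of the two-class posterior.

    Intended for small instances only (e.g. two definitions, coarse
    grid); refuses lattices exceeding ``max_points`` total grid points.
    Grid nodes are cell midpoints of each parameter's truncation range,
    weighted by the (untruncated) Beta prior density, so a flat prior
    with zero observations returns the prior itself.
    """
    counts = _coerce_counts(pattern_counts)
    j = counts.n_definitions
    priors = LCMPriors.default(j) if priors is None else priors
    if priors.n_definitions != j:
        raise SchemaError("priors do not match the number of definitions")
    n_params = 1 + 2 * j
    if grid_resolution < 2:
        raise ArgumentError("grid_resolution must be >= 2")
    if grid_resolution**n_params > max_points:
        raise GridSizeError(
            f"{grid_resolution}^{n_params} grid points exceed the "
            f"documented limit of {max_points}"
        )

    specs = [p for _, p in priors.param_list()]
    grids = [
        p.lower + (np.arange(grid_resolution) + 0.5) * (p.upper - p.lower)
        / grid_resolution
        for p in specs
    ]

    def axis(i: int, arr: np.ndarray) -> np.ndarray:
        shape = [1] * n_params
        shape[i] = len(arr)
        return arr.reshape(shape)

    log_post = np.zeros((1,) * n_params)
    for i, (g, p) in enumerate(zip(grids, specs)):
        log_post = log_post + axis(i, beta_dist.logpdf(g, p.a, p.b))

    pi_g = axis(0, grids[0])
    y = pattern_matrix(j)
    for k, n_k in enumerate(counts.counts):
        if n_k == 0:
            continue
        p1 = pi_g.copy()
        p0 = 1.0 - pi_g
        for jj in range(j):
            se_g = axis(1 + jj, grids[1 + jj])
            sp_g = axis(1 + j + jj, grids[1 + j + jj])
            p1 = p1 * (se_g if y[k, jj] else (1.0 - se_g))
            p0 = p0 * ((1.0 - sp_g) if y[k, jj] else sp_g)
        log_post = log_post + n_k * np.log(p1 + p0)

    log_post = np.broadcast_to(
        log_post, (grid_resolution,) * n_params
    ).astype(float)
    post = np.exp(log_post - logsumexp(log_post))
    post = post / post.sum()
    return GridPosterior(_param_names(j), grids, post)


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    ``chains`` is (n_chains, n_draws). Classic between/within-chain
    computation: with W the mean within-chain variance and B/n the
    variance of the chain means, R-hat = sqrt(((n-1)/n W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ArgumentError("need a (n_chains >= 2, n_draws) array")
    m, n = chains.shape
    if n < 10:
        raise ArgumentError(f"need at least 10 draws per chain, got {n}")
    within = chains.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        raise DegenerateInputError("zero within-chain variance in all chains")
    b_over_n = chains.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))
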