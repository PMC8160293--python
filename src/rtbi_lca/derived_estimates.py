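"""Closed-form quantities derived from the latent class parameters.

Predictive values follow from Bayes' rule at a given prevalence;
measurement-error-corrected incidence uses the Rogan-Gladen estimator,
the standard crude-rate correction that needs only sensitivity and
specificity; and the adjusted median time to recurrence reweights each
suspected event by the probability it is real — the probability the
patient truly had an index TBI times the posterior probability of true
recurrence given the observed response pattern.

All of ``ppv``/``npv``/``adjust_crude_incidence`` broadcast over numpy
arrays, so draw-wise computation (feeding posterior draws of pi, Se, Sp
and summarizing afterwards) is a one-liner and is what the pipeline
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blcm import LCMParams, PosteriorDraws, pattern_likelihood
from .case_ascertainment import pattern_matrix
from .errors import (
    ArgumentError,
    EmptyInputError,
    IdentifiabilityError,
    UndefinedValueError,
)
from .pooling import PooledEstimate, summarize

__all__ = [
    "AdjustedIncidence",
    "ppv",
    "npv",
    "classification_probability",
    "adjust_crude_incidence",
    "weighted_median",
    "adjusted_median_time",
]


@dataclass(frozen=True)
class AdjustedIncidence:
    """Apparent (crude) and measurement-error-adjusted one-year risk."""

    apparent: float
    adjusted: float
    se_used: float
    sp_used: float
    clamped: bool = False


def _check_unit_interval(**kwargs) -> None:
    for name, v in kwargs.items():
        if np.any((np.asarray(v) <= 0.0) | (np.asarray(v) >= 1.0)):
            raise ArgumentError(f"{name} must lie strictly inside (0, 1)")


def ppv(pi, se, sp):
    """Positive predictive value pi*Se / (pi*Se + (1-pi)(1-Sp)).

    Broadcasts over arrays (e.g. posterior draws).
    """
    _check_unit_interval(pi=pi, se=se, sp=sp)
    pi, se, sp = (np.asarray(x, dtype=float) for x in (pi, se, sp))
    num = pi * se
    den = num + (1.0 - pi) * (1.0 - sp)
    if np.any(den == 0.0):
        raise UndefinedValueError("no positives are possible at these parameters")
    out = num / den
    return float(out) if out.ndim == 0 else out


def npv(pi, se, sp):
    """Negative predictive value (1-pi)*Sp / ((1-pi)*Sp + pi*(1-Se))."""
    _check_unit_interval(pi=pi, se=se, sp=sp)
    pi, se, sp = (np.asarray(x, dtype=float) for x in (pi, se, sp))
    num = (1.0 - pi) * sp
    den = num + pi * (1.0 - se)
    if np.any(den == 0.0):
        raise UndefinedValueError("no negatives are possible at these parameters")
    out = num / den
    return float(out) if out.ndim == 0 else out


def classification_probability(pattern, params: LCMParams) -> float:
    """Posterior probability of true recurrence given a response pattern.

    Bayes' rule within the two-class model: the class-1 branch of the
    pattern likelihood over the whole likelihood.
    """
    y = np.asarray(pattern, dtype=int)
    total = pattern_likelihood(params, y)
    if total == 0.0:
        raise UndefinedValueError(f"pattern {tuple(y)} has zero likelihood")
    branch1 = params.pi * float(
        np.prod(np.where(y == 1, params.se, 1.0 - params.se))
    )
    return branch1 / total


def adjust_crude_incidence(apparent, se, sp) -> AdjustedIncidence:
    """Rogan-Gladen correction of an apparent one-year risk.

    adjusted = (apparent + Sp - 1) / (Se + Sp - 1), clamped to [0, 1]
    (with the clamp flagged). ``apparent`` must be on the proportion
    scale; a rate per 100 person-years divides by 100 first.
    """
    apparent = float(apparent)
    se = float(se)
    sp = float(sp)
    if se + sp <= 1.0:
        raise IdentifiabilityError(
            f"Se + Sp must exceed 1 to invert the misclassification, "
            f"got {se} + {sp}"
        )
    if not (0.0 <= apparent <= 1.0):
        raise ArgumentError(f"apparent risk must be in [0, 1], got {apparent}")
    raw = (apparent + sp - 1.0) / (se + sp - 1.0)
    adjusted = min(max(raw, 0.0), 1.0)
    return AdjustedIncidence(
        apparent=apparent,
        adjusted=adjusted,
        se_used=se,
        sp_used=sp,
        clamped=(adjusted != raw),
    )


def weighted_median(days, weights) -> float:
    """Smallest day whose cumulative weight reaches half the total weight."""
    days = np.asarray(days, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if days.shape != weights.shape:
        raise ArgumentError("days and weights must have equal length")
    if np.any(weights < 0):
        raise ArgumentError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise EmptyInputError("total event weight is zero")
    order = np.argsort(days, kind="stable")
    cum = np.cumsum(weights[order])
    k = int(np.searchsorted(cum, total / 2.0))
    return float(days[order][min(k, len(days) - 1)])


def adjusted_median_time(
    days,
    weights=None,
    *,
    patterns=None,
    incident_probs=None,
    draws: PosteriorDraws | None = None,
    n_draws: int = 500,
) -> float | PooledEstimate:
    """Median time to recurrence, down-weighting doubtful events.

    With precomputed ``weights`` (P(true index TBI) x P(true recurrence |
    pattern)), returns the weighted median directly. With posterior
    ``draws`` plus each event's ``patterns`` (response-pattern index) and
    ``incident_probs``, the weights are recomputed per retained draw and
    the per-draw medians summarized as median + 95% HDI.
    """
    days = np.asarray(days, dtype=float)
    if draws is None:
        if weights is None:
            weights = np.ones_like(days)
        return weighted_median(days, weights)
    if patterns is None or incident_probs is None:
        raise ArgumentError(
            "draw-wise adjustment needs patterns and incident_probs per event"
        )
    patterns = np.asarray(patterns, dtype=int)
    incident_probs = np.asarray(incident_probs, dtype=float)
    se_names = [n for n in draws.names if n.startswith("se_")]
    j = len(se_names)
    y = pattern_matrix(j)
    flat = draws.draws.reshape(-1, len(draws.names))
    sub = flat[np.linspace(0, len(flat) - 1, min(n_draws, len(flat))).astype(int)]
    cols = {name: k for k, name in enumerate(draws.names)}
    se_idx = [cols[n] for n in se_names]
    sp_idx = [cols["sp_" + n[3:]] for n in se_names]
    medians = np.empty(len(sub))
    for r, row in enumerate(sub):
        pi, se, sp = row[cols["pi"]], row[se_idx], row[sp_idx]
        p1 = pi * np.prod(np.where(y == 1, se, 1.0 - se), axis=1)
        p0 = (1.0 - pi) * np.prod(np.where(y == 1, 1.0 - sp, sp), axis=1)
        class_prob = p1 / (p1 + p0)
        w = incident_probs * class_prob[patterns]
        medians[r] = weighted_median(days, w)
    return summarize(medians, name="adjusted_median_time")
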