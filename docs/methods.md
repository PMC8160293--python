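# Methods

## Problem and estimands

A patient who has had an index traumatic brain injury (TBI) may have a
recurrence (rTBI) within the following year. In administrative claims,
recurrence can only be *suspected* through case definitions built from
diagnostic and billing codes, and none of them is a gold standard. The
estimands are the one-year rTBI risk π among true index-TBI patients,
the sensitivity Seⱼ and specificity Spⱼ of four case definitions, and
quantities derived from them (PPV/NPV, corrected incidence, median time
to recurrence), by age group (children < 18, adults 18–64, elderly ≥ 65)
and overall.

## Case definitions and ascertainment window

Four definitions are evaluated, in a fixed bit order: (1) outpatient
physician claim with a TBI diagnosis; (2) emergency-room physician claim
with a TBI diagnosis; (3) any TBI diagnosis in the hospital discharge
abstract database (DAD); (4) a head-imaging billing claim (CT/MRI/skull
x-ray codes 08258, 08259, 08570, 08010, 08013) paired with a physician
claim carrying *any* trauma diagnosis (ICD-9 families 8XX/91X/92X/93X,
prefix-matched on dot-stripped codes) dated within 1 day. Hospital
inpatient physician claims are parsed but feed no definition. TBI code
lists default to the common surveillance families (ICD-9 800–804,
850–854, 950.1–950.3, 959.01; ICD-10 S02, S06, S07, S09.7–S09.9, T90.2,
T90.5) and are overridable per definition — exact production lists vary
by jurisdiction, so these defaults are approximations by design.

Claims in the first 7 days after the index date are attributed to the
index episode; the ascertainment window is days 7–365 (both endpoints
configurable; setting the lower bound to 30 reproduces the
follow-up-noise sensitivity analysis). The radiology definition's event
day is the imaging claim's day, and both members of the pair must fall
inside the window. Person-time runs from index to the earliest of first
qualifying claim, cohort exit, or day 365, with a person-year equal to
365 days exactly because the window is defined in days.

Free parameters of a K-class model with J definitions are counted as one
incidence parameter plus one response probability per class per
definition, 1 + K·J: 9 for the two-class model (15 degrees of freedom
available from 16 patterns), 13 for the three-class analogue. The
three-class model is deliberately not fitted — with these data
structures it is not estimable without informative priors that do not
exist in the literature — only its arithmetic is exposed.

## The latent class model

Two classes (no rTBI / rTBI), conditional independence of the four
definitions given class. Pattern probabilities as in the README. Priors
are Beta(1, 1) truncated to ranges that act as soft identifiability
constraints:

| parameter | truncation | rationale |
|---|---|---|
| π | (0, 0.25) | one-year recurrence risk is far below 25% |
| Spⱼ, all j | (0.7, 1) | claims definitions are known to be specific |
| Se_er, Se_dad | (0.02, 0.9) | keeps the two constrained tests informative |
| other Seⱼ | (0, 1) | unconstrained |

The published analysis states such constraints exist but not their
numeric ranges; the values above are this package's reconstruction and
every range is overridable (the prior-sensitivity harness varies them).
Label switching is prevented by rejecting Gibbs updates that would give
Se + Sp ≤ 1 on the constrained definitions (ER, DAD) rather than by
post-hoc relabelling; with the default ranges such rejections are rare,
so the distortion of the stationary distribution is negligible and the
sampler still matches an independent grid-integration oracle to < 0.02
on marginal means.

### Sampling

Gibbs with latent-class data augmentation. Aggregated pattern counts are
the sufficient statistic without covariates: each pattern's count is
split Binomial between classes given current parameters, then π, Seⱼ,
Spⱼ are drawn from truncated-Beta full conditionals via the inverse
regularized incomplete beta function (draws clipped 1e-12 inside the
truncation bounds for numerical safety). With the sex covariate, the
logistic layer logit(πᵢ) = β₀ + β_sex·maleᵢ has no conjugate update;
(β₀, β_sex) move by a joint random-walk Metropolis step with a N(0, 5²)
prior per coefficient, the proposal scale adapted only during burn-in
(targeting roughly 0.2–0.45 acceptance), and proposals whose implied
population-average prevalence leaves the π truncation are rejected.
Sufficient statistics are counts by (pattern × sex), so cost is
independent of cohort size. The reported `pi` under covariates is the
population-average prevalence at the current coefficients.

Defaults are 3 chains × 20,000 iterations with 5,000 burn-in, matching
the production design; the pipeline's desk-scale default is 2 × 3,000
with 1,000 burn-in, which suffices for these posteriors (R-hat < 1.1,
checked per parameter with the classic between/within-chain potential
scale reduction factor; non-convergence is surfaced as a warning and in
the draws object, never silently). Chains are seeded from a
`SeedSequence` spawn of the master seed, making every fit bitwise
reproducible.

### Brute-force oracle

`brute_force_posterior` evaluates the exact posterior on a midpoint
lattice over all 1 + 2J parameters (refusing more than 2²⁴ grid points)
and is used as an independent check of the sampler on two-definition
instances. It shares nothing with the Gibbs path beyond the likelihood
definition.

## Propagating incident-cohort uncertainty

The upstream incident-TBI analysis yields, for each patient, a posterior
probability of truly having had an index TBI. M predicted cohorts are
drawn by including each patient independently with that probability
(production M = 1,000; pipeline default M = 50 — a deliberate
desk-scale choice that leaves pooled medians essentially unchanged while
keeping a full run in minutes). The model is refitted per cohort with
deterministically derived per-cohort seeds; individual fit failures are
recorded, not fatal. Post-burn-in draws are thinned to an equal budget
per cohort (default 200) and concatenated — the standard
multiple-imputation-style mixture of posteriors; whether the original
analysis pooled equal budgets or all retained draws is unstated, so the
budget is configurable. Age strata are combined by resampling each
stratum's pool in proportion to its mean predicted cohort size.
Summaries are posterior medians with 95% highest-density intervals
computed as the shortest contiguous interval on sorted draws (no
unimodality machinery assumed).

## Model checking

Conditional independence is checked by posterior predictive pairwise
agreement: for each of the six definition pairs the raw concordance
P(yⱼ = yₖ) in the data is compared with its distribution over replicate
datasets simulated from retained draws. Raw concordance is used rather
than kappa because the check compares like with like. The Bayesian
p-value counts ties at half weight (mid-p), which keeps its distribution
close to uniform on discrete data; pairs with p outside (0.05, 0.95) are
flagged (the published account gives the check's direction but no
cutoff; 0.05/0.95 is this package's choice). In the pipeline the check
runs per predicted cohort (first `ppc_cohorts` fits) and reports the
median p per pair. The misfit signature is informative but not
pair-localised: when extra dependence between two definitions is
injected, the refitted model partially absorbs it into Se/Sp and the
extreme p-values can surface on *other* pairs — the flag, not its
location, is the diagnostic.

Prior sensitivity refits under a grid of alternative truncation settings
and flags any parameter whose 95% interval no longer overlaps the
primary fit's.

## Derived estimates

PPV = πSe / (πSe + (1−π)(1−Sp)) and NPV = (1−π)Sp / ((1−π)Sp + π(1−Se)),
computed draw-wise over the pooled posterior and then summarized
(plug-in point-estimate mode is the same function applied to scalars).
The crude-risk correction is the Rogan–Gladen estimator
(apparent + Sp − 1)/(Se + Sp − 1), clamped to [0, 1] with the clamp
flagged; rates per 100 person-years are divided by 100 before correction
(small-rate approximation of risk by rate). The adjusted median time to
recurrence weights each suspected event by P(true index TBI) ×
P(true rTBI | response pattern) and takes the smallest day whose
cumulative weight reaches half the total (crude medians use the matching
lower-median convention, so unit weights reduce exactly to the crude
statistic); with posterior draws the weights are recomputed per draw and
the per-draw medians summarized.

## The synthetic-data generator

The generator emulates what the analysis assumes about the real claims
environment:

* a dynamic cohort over a 15-year window (entry at study start; a
  configurable fraction, default 10%, exits early at a uniform time —
  the real cohort's censoring fraction is unpublished, so this default
  is arbitrary and flagged as such);
* index TBI episodes with age-specific probabilities, a 10% "most
  severe" share, and membership probabilities Beta-distributed around
  0.85 for true index cases (zero otherwise) standing in for the
  upstream incident model's posterior;
* latent one-year recurrence with per-(age × severity) marginal risks
  echoing the published adjusted estimates (children 1.69, adults 3.57,
  elderly 9.03 per 100), severity risk ratios per age group, and a male
  log-odds shift of log 1.4; the female baseline is back-solved so the
  configured *marginal* risk holds whatever the sex effect;
* recurrence days from a discretized exponential truncated to [7, 365]
  with untruncated medians 120/75/109 days by age group (the published
  account reports medians only, so the distributional family is this
  package's choice);
* definition signals conditionally independent given the latent class:
  Se-Bernoulli claim-sets at the true recurrence day; false-positive
  claim-sets with total probability 1 − Spⱼ whose mass is concentrated
  in days 7–30 (geometric decay, ratio 0.85) up to the early-noise
  budget `followup_noise_rate × Σ decay` and uniform over days 7–365
  beyond it — so marginal Se/Sp always match the configured operating
  points (verified within 3 binomial SE at n ≥ 50,000) while early
  follow-up noise reproduces the phenomenon the 30-day exclusion
  analysis targets;
* at most one recurrence per patient (the analysis design assesses
  single recurrences only).

What it does **not** emulate: external causes of injury, hospital length
of stay, code-assignment noise beyond the Se/Sp mechanism, seasonal or
secular trends, correlated care-seeking (conditional dependence between
definitions), and multiple recurrences. Passing tests therefore
demonstrate correctness of the estimator under its own assumptions and
its robustness behaviours (prior sensitivity, PPC flagging injected
dependence), not performance on real claims.

## Numerical and design notes

* Truncated-Beta draws via inverse CDF on `betainc`/`betaincinv`;
  degenerate truncations collapse to the nearest bound.
* The 16-pattern likelihood is normalized to 1 by construction;
  property-tested across random parameter draws.
* Pattern bit order is most-significant-first (outpatient, ER, DAD,
  radiology): pattern 0b1001 means outpatient and radiology positive.
* Stage and cohort seeds fan out from the master seed through
  `SeedSequence` (stage names hashed by CRC32), so end-to-end runs are
  checksum-reproducible.
* Frequentist coverage of the 95% credible intervals at the recovery
  test's conditions (n = 50,000, π = 0.05, an insensitive DAD
  definition) sits near 93%, with the posterior quantile of the truth
  centred at 0.5 across replicates — slight undercoverage intrinsic to
  weak identifiability at a low-prevalence corner, not sampler bias
  (the sampler matches the grid oracle).

## Limitations

The constraints' numeric ranges, the pooling budget, and the PPC cutoff
are reconstructions where the published account is silent; all are
configurable and exercised by the sensitivity harness. The Rogan–Gladen
correction treats the union crude risk and a single (Se, Sp) pair as
exchangeable with the per-definition quantities, which is exact only
when applied per definition. The logistic layer puts the sex effect on
prevalence only; sex-specific Se/Sp are not modelled.
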