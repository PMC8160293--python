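"""Latent class model: likelihood, Gibbs sampler, grid oracle, R-hat."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtbi_lca.blcm import (
    BetaPrior,
    LCMParams,
    LCMPriors,
    MCMCSettings,
    brute_force_posterior,
    fit_two_class,
    gelman_rubin,
    pattern_likelihood,
    pattern_probabilities,
)
from rtbi_lca.case_ascertainment import DEFINITIONS, ResponsePatternCounts, pattern_matrix
from rtbi_lca.errors import (
    ArgumentError,
    DegenerateInputError,
    EmptyInputError,
    GridSizeError,
)

FLAT_PRIORS_4 = LCMPriors(
    pi=BetaPrior(),
    se=tuple(BetaPrior() for _ in range(4)),
    sp=tuple(BetaPrior(lower=0.5) for _ in range(4)),
    joint_constrained=(),
)

PRIORS_2 = LCMPriors(
    pi=BetaPrior(upper=0.25),
    se=(BetaPrior(), BetaPrior()),
    sp=(BetaPrior(lower=0.7), BetaPrior(lower=0.7)),
    joint_constrained=(),
)


class TestLikelihood:
    def test_perfect_tests_concentrate_on_two_patterns(self):
        eps = 1e-12
        params = LCMParams(pi=0.3, se=[1 - eps] * 4, sp=[1 - eps] * 4)
        assert pattern_likelihood(params, (1, 1, 1, 1)) == pytest.approx(0.3)
        assert pattern_likelihood(params, (0, 0, 0, 0)) == pytest.approx(0.7)
        assert pattern_likelihood(params, (1, 0, 0, 0)) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_cell(self):
        params = LCMParams(pi=0.1, se=[0.5] * 4, sp=[0.9] * 4)
        # 0.1 * 0.5^4 + 0.9 * 0.9^4
        assert pattern_likelihood(params, (0, 0, 0, 0)) == pytest.approx(0.59674)

    @given(
        st.floats(0.01, 0.99),
        st.lists(st.floats(0.01, 0.99), min_size=4, max_size=4),
        st.lists(st.floats(0.01, 0.99), min_size=4, max_size=4),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_normalization_over_all_patterns(self, pi, se, sp):
        probs = pattern_probabilities(pi, np.array(se), np.array(sp))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ArgumentError):
            LCMParams(pi=0.0, se=[0.5] * 4, sp=[0.5] * 4)
        with pytest.raises(ArgumentError):
            LCMParams(pi=0.5, se=[1.0] * 4, sp=[0.5] * 4)


class TestGibbsSampler:
    def test_degenerate_recovery_with_near_perfect_tests(self):
        """Data from perfect tests at pi = 0.2: the posterior must pin pi
        near 0.2 and push all Se/Sp medians above 0.99."""
        rng = np.random.default_rng(0)
        n = 10_000
        cases = rng.binomial(n, 0.2)
        counts = np.zeros(16, dtype=int)
        counts[0b1111] = cases
        counts[0b0000] = n - cases
        fit = fit_two_class(
            counts,
            priors=FLAT_PRIORS_4,
            settings=MCMCSettings(n_chains=2, n_iterations=2000, burn_in=500, seed=1),
        )
        assert np.median(fit.get("pi")) == pytest.approx(0.2, abs=0.02)
        for d in DEFINITIONS:
            assert np.median(fit.get(f"se_{d}")) > 0.99
            assert np.median(fit.get(f"sp_{d}")) > 0.99

    def test_draws_respect_truncations_and_label_guard(self):
        rng = np.random.default_rng(1)
        probs = pattern_probabilities(
            0.05, np.array([0.3, 0.45, 0.12, 0.8]), np.array([0.98, 0.99, 0.995, 0.99])
        )
        counts = rng.multinomial(20_000, probs)
        priors = LCMPriors()  # default truncations, er/dad jointly constrained
        fit = fit_two_class(
            counts,
            priors=priors,
            settings=MCMCSettings(n_chains=2, n_iterations=1500, burn_in=500, seed=2),
        )
        for name, prior in priors.param_list():
            d = fit.get(name)
            assert d.min() >= prior.lower
            assert d.max() <= prior.upper
        for j in priors.joint_constrained:
            d = DEFINITIONS[j]
            assert (fit.get(f"se_{d}") + fit.get(f"sp_{d}") > 1.0).all()

    def test_seed_determinism(self):
        counts = np.array([500, 20, 30, 8, 25, 9, 7, 3] + [2] * 8)
        s = MCMCSettings(n_chains=2, n_iterations=500, burn_in=100, seed=42)
        f1 = fit_two_class(counts, priors=FLAT_PRIORS_4, settings=s)
        f2 = fit_two_class(counts, priors=FLAT_PRIORS_4, settings=s)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_empty_counts_rejected(self):
        with pytest.raises(EmptyInputError):
            fit_two_class(np.zeros(16, dtype=int))

    def test_covariate_sex_odds_ratio_recovery(self):
        """With a true male odds ratio of 1.4 on latent prevalence at
        n = 50,000, the posterior median of exp(beta_sex) lands in
        (1.2, 1.65)."""
        from scipy.special import expit, logit

        rng = np.random.default_rng(3)
        n = 50_000
        male = rng.random(n) < 0.55
        pi_i = expit(logit(0.04) + np.log(1.4) * male)
        c = rng.random(n) < pi_i
        se = np.array([0.3, 0.45, 0.12, 0.8])
        sp = np.array([0.98, 0.99, 0.995, 0.99])
        flags = rng.random((n, 4)) < np.where(c[:, None], se, 1 - sp)
        fit = fit_two_class(
            flags,
            covariate_male=male,
            settings=MCMCSettings(n_chains=2, n_iterations=4000, burn_in=1500, seed=11),
        )
        or_med = float(np.exp(np.median(fit.get("beta_sex"))))
        assert 1.2 < or_med < 1.65
        assert fit.accept_rate is not None and 0.05 < fit.accept_rate < 0.9


class TestBruteForce:
    def test_flat_prior_no_data_returns_prior(self):
        grid = brute_force_posterior(np.zeros(4, dtype=int), 15, priors=PRIORS_2)
        g, w = grid.marginal("pi")
        assert np.allclose(w, 1.0 / 15, atol=1e-12)
        assert grid.marginal_mean("pi") == pytest.approx(0.125, abs=1e-6)

    def test_grid_size_refused(self):
        with pytest.raises(GridSizeError):
            brute_force_posterior(np.zeros(16, dtype=int), 25)  # 25^9 points

    def test_saturated_positives_concentrate_pi_near_one(self):
        priors = LCMPriors(
            pi=BetaPrior(),
            se=(BetaPrior(lower=0.9), BetaPrior(lower=0.9)),
            sp=(BetaPrior(lower=0.7), BetaPrior(lower=0.7)),
            joint_constrained=(),
        )
        counts = np.array([0, 0, 0, 200])  # everyone pattern 11
        grid = brute_force_posterior(counts, 21, priors=priors)
        assert grid.marginal_mean("pi") > 0.8

    def test_mcmc_matches_grid_on_toy_data(self):
        """Sampler vs independent grid integration on 2-definition data."""
        counts = np.array([160, 15, 12, 13])
        grid = brute_force_posterior(counts, 25, priors=PRIORS_2)
        fit = fit_two_class(
            counts,
            priors=PRIORS_2,
            settings=MCMCSettings(n_chains=3, n_iterations=6000, burn_in=1500, seed=7),
        )
        for name in fit.names:
            assert float(fit.get(name).mean()) == pytest.approx(
                grid.marginal_mean(name), abs=0.02
            ), name


class TestGelmanRubin:
    def test_same_distribution_below_threshold(self):
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((3, 5000))
        assert gelman_rubin(chains) < 1.05

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((2, 2000))
        chains[1] += 5.0
        assert gelman_rubin(chains) > 1.1

    def test_matches_reference_implementation(self):
        """Cross-check against the arviz rank-normalized R-hat on
        well-mixed chains, where the two versions nearly coincide."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((4, 4000))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ArgumentError):
            gelman_rubin(np.zeros((1, 100)))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            gelman_rubin(np.ones((3, 100)))
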