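"""Priors, likelihood, Metropolis-Hastings sampler and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from raygrowth import (
    MCMC_PRESETS,
    McmcConfig,
    PriorSet,
    SizeAtAgeRecord,
    SpeciesTemplate,
    generate_sample,
    geweke_diagnostic,
    log_likelihood,
    log_prior,
    sample_posterior,
    summarize_posterior,
)
from raygrowth.bayes import McmcError
from conftest import grid_posterior_medians


class TestPriors:
    def test_natural_scale_mean_is_77(self):
        priors = PriorSet()
        assert priors.w_inf_natural_mean == pytest.approx(77.0, abs=1e-9)

    def test_log_location_alternative(self):
        priors = PriorSet(log_location_mean=True)
        assert priors.w_inf_log_location == pytest.approx(math.log(77.0))
        # natural mean then exceeds 77 by the lognormal correction factor
        assert priors.w_inf_natural_mean == pytest.approx(77.0 * math.exp(0.125))

    def test_outside_support_gives_minus_inf(self):
        priors = PriorSet()
        assert log_prior((100.0, 1.2, 25.0), priors) == -math.inf
        assert log_prior((-5.0, 0.1, 25.0), priors) == -math.inf
        assert log_prior((100.0, 0.1, -1.0), priors) == -math.inf

    def test_matches_scipy_density_oracle(self):
        priors = PriorSet()
        got = log_prior((77.0, 0.119, 25.0), priors)
        expected = (
            stats.lognorm.logpdf(77.0, s=0.5, scale=math.exp(math.log(77) - 0.125))
            + stats.beta.logpdf(0.119, 21.9, 162.3)
            + stats.invgamma.logpdf(25.0, 0.01, scale=0.01)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_densities_integrate_to_one(self):
        """Numerical spot-check that each marginal prior is a proper density."""
        priors = PriorSet()
        base = log_prior((77.0, 0.119, 25.0), priors)
        w = np.linspace(0.5, 3000.0, 200_001)
        pw = np.exp([log_prior((float(x), 0.119, 25.0), priors) - base for x in w[::500]])
        # quadrature on the coarse grid of the w_inf marginal (others held fixed)
        w_coarse = w[::500]
        mass = np.trapezoid(pw, w_coarse) * math.exp(base) / math.exp(
            stats.beta.logpdf(0.119, 21.9, 162.3) + stats.invgamma.logpdf(25.0, 0.01, scale=0.01)
        )
        assert mass == pytest.approx(1.0, abs=5e-3)
        k = np.linspace(1e-4, 1 - 1e-4, 20_001)
        pk = stats.beta.pdf(k, priors.k_alpha, priors.k_beta)
        assert np.trapezoid(pk, k) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorSet(k_alpha=0.0)


class TestLogLikelihood:
    def test_single_perfect_record(self):
        rec = [SizeAtAgeRecord("x", 5.0, 100 - 80 * math.exp(-1.0))]
        ll = log_likelihood((100.0, 0.2, 1.0), rec, w0=20.0)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_monotone_decrease_as_variance_shrinks_with_residual(self):
        rec = [SizeAtAgeRecord("x", 5.0, 60.0)]  # nonzero residual
        lls = [log_likelihood((100.0, 0.2, v), rec, w0=20.0) for v in (1e-2, 1e-4, 1e-6)]
        assert lls[0] > lls[1] > lls[2]

    def test_additivity_under_duplication(self):
        tpl = SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=1, age_max=10, n=20, noise_sd=3)
        data = generate_sample(tpl, seed=2)
        one = log_likelihood((95.0, 0.25, 9.0), data, w0=20.0)
        two = log_likelihood((95.0, 0.25, 9.0), data + data, w0=20.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nonpositive_variance(self):
        rec = [SizeAtAgeRecord("x", 5.0, 60.0)]
        assert log_likelihood((100.0, 0.2, 0.0), rec, w0=20.0) == -math.inf


class TestSampler:
    def test_retained_draw_count_of_reference_config(self):
        assert MCMC_PRESETS["paper"].retained == 19_000
        assert MCMC_PRESETS["desk"].retained == 9_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=1000, burn_in=2000, thin=1)
        with pytest.raises(ValueError):
            McmcConfig(iterations=50_000, burn_in=5_000, thin=0)

    def test_reproducible_bit_for_bit(self):
        tpl = SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=1, age_max=15, n=30, noise_sd=3)
        data = generate_sample(tpl, seed=9)
        cfg = McmcConfig(iterations=20_000, burn_in=2_000, thin=10, seed=77)
        a = sample_posterior(data, PriorSet(), cfg, w0=20.0)
        b = sample_posterior(data, PriorSet(), cfg, w0=20.0)
        assert np.array_equal(a.w_inf, b.w_inf)
        assert np.array_equal(a.k, b.k)
        assert np.array_equal(a.sigma2, b.sigma2)
        assert a.acceptance_rate == b.acceptance_rate

    def test_parameter_recovery_n500(self):
        tpl = SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=1, age_max=20, n=500, noise_sd=3)
        data = generate_sample(tpl, seed=42)
        chain = sample_posterior(data, PriorSet(), MCMC_PRESETS["desk"], w0=20.0)
        summ = summarize_posterior(chain)
        assert 95 <= summ["w_inf"]["median"] <= 105
        assert 0.18 <= summ["k"]["median"] <= 0.22
        # credibility intervals contain the generating values
        assert summ["w_inf"]["ci_lower"] <= 100 <= summ["w_inf"]["ci_upper"]
        assert summ["k"]["ci_lower"] <= 0.2 <= summ["k"]["ci_upper"]
        assert 0 < chain.acceptance_rate < 1
        assert np.all(chain.k > 0) and np.all(chain.k < 1)
        assert np.all(chain.w_inf > 0) and np.all(chain.sigma2 > 0)

    def test_zero_information_data_reproduces_priors(self):
        """With one informative-free observation and a huge fixed variance,
        the posterior of (w_inf, k) collapses back to the priors."""
        data = [SizeAtAgeRecord("x", float(a), 50.0) for a in (1, 2, 3, 4, 5)]
        cfg = McmcConfig(iterations=200_000, burn_in=20_000, thin=20, seed=5)
        chain = sample_posterior(data, PriorSet(), cfg, w0=20.0, sigma2_fixed=1e8)
        priors = PriorSet()
        rng = np.random.default_rng(6)
        prior_w = rng.lognormal(priors.w_inf_log_location, priors.w_inf_log_sd, 200_000)
        prior_k = rng.beta(priors.k_alpha, priors.k_beta, 200_000)
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(chain.w_inf, q) == pytest.approx(
                np.quantile(prior_w, q), rel=0.05
            )
            assert np.quantile(chain.k, q) == pytest.approx(
                np.quantile(prior_k, q), rel=0.05
            )

    def test_grid_oracle_equivalence_small_data(self, small_noisy_dataset):
        """MH medians agree with brute-force grid integration within 2%."""
        priors = PriorSet()
        w_grid = np.linspace(60, 220, 240)
        k_grid = np.linspace(0.02, 0.6, 240)
        v_grid = np.geomspace(0.5, 600, 200)
        gw, gk = grid_posterior_medians(small_noisy_dataset, 20.0, priors, w_grid, k_grid, v_grid)
        chain = sample_posterior(small_noisy_dataset, priors, MCMC_PRESETS["desk"], w0=20.0)
        summ = summarize_posterior(chain)
        assert abs(summ["w_inf"]["median"] / gw - 1) < 0.02
        assert abs(summ["k"]["median"] / gk - 1) < 0.02

    def test_too_few_records_rejected(self):
        data = [SizeAtAgeRecord("x", 1.0, 30.0)] * 3
        with pytest.raises(McmcError):
            sample_posterior(data, PriorSet(), MCMC_PRESETS["sim"], w0=20.0)

    def test_interval_coverage_for_k(self):
        """Across replicated datasets the 95% interval for k covers the
        generating value at roughly nominal rate."""
        tpl = SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=1, age_max=20, n=50, noise_sd=4)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            data = generate_sample(tpl, seed=3000 + rep)
            cfg = McmcConfig(iterations=50_000, burn_in=5_000, thin=10, seed=4000 + rep)
            summ = summarize_posterior(sample_posterior(data, PriorSet(), cfg, w0=20.0))
            hits += summ["k"]["ci_lower"] <= 0.2 <= summ["k"]["ci_upper"]
        assert 0.90 * n_rep <= hits <= n_rep


class TestGeweke:
    def test_constant_chain_is_error(self):
        with pytest.raises(McmcError):
            geweke_diagnostic(np.full(1000, 3.0))

    def test_short_chain_is_error(self):
        with pytest.raises(McmcError):
            geweke_diagnostic(np.random.default_rng(0).standard_normal(50))

    def test_iid_chain_small_z(self):
        chain = np.random.default_rng(8).standard_normal(10_000)
        assert abs(geweke_diagnostic(chain)) < 3

    def test_ramp_chain_large_z(self):
        assert abs(geweke_diagnostic(np.linspace(0, 1, 10_000))) > 10


class TestSummarize:
    def test_degenerate_draws(self):
        from raygrowth import PosteriorChain

        chain = PosteriorChain(
            w_inf=np.full(2000, 5.0), k=np.full(2000, 5.0), sigma2=np.full(2000, 5.0),
            acceptance_rate=0.3,
        )
        s = summarize_posterior(chain)
        assert s["w_inf"] == {"median": 5.0, "ci_lower": 5.0, "ci_upper": 5.0}

    def test_uniform_draw_quantiles(self):
        from raygrowth import PosteriorChain

        u = np.random.default_rng(4).random(100_000)
        chain = PosteriorChain(w_inf=u, k=u, sigma2=u, acceptance_rate=0.3)
        s = summarize_posterior(chain)["w_inf"]
        assert s["median"] == pytest.approx(0.5, abs=0.005)
        assert s["ci_lower"] == pytest.approx(0.025, abs=0.005)
        assert s["ci_upper"] == pytest.approx(0.975, abs=0.005)

    def test_too_few_draws(self):
        from raygrowth import PosteriorChain

        chain = PosteriorChain(
            w_inf=np.ones(10), k=np.ones(10), sigma2=np.ones(10), acceptance_rate=0.3
        )
        with pytest.raises(McmcError):
            summarize_posterior(chain)
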