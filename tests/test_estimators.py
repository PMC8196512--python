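import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from canopyk import (
    CanopyObservation,
    Dataset,
    MCMCConfig,
    OptimizerConfig,
    PriorSpec,
    SyntheticConfig,
    beer_lambert_mean,
    beta_loglik,
    fit_logtlm,
    fit_lse,
    fit_mle_beta,
    fit_mle_normal,
    log_posterior,
    normal_loglik,
    numeric_hessian,
    run_metropolis,
    simulate_dataset,
    sse,
    summarize_posterior,
)
from canopyk.errors import (
    ConfigurationError,
    DomainError,
    NumericError,
    ValidationError,
)
from conftest import make_noiseless_dataset


def _single(lai, fpari, genotype="A"):
    return Dataset.from_observations(
        [CanopyObservation(genotype, a, f) for a, f in zip(lai, fpari)]
    )


class TestBeerLambertMean:
    def test_zero_lai(self):
        assert beer_lambert_mean(0.7, 0.0) == 0.0

    def test_zero_k(self):
        assert beer_lambert_mean(0.0, 5.0) == 0.0

    def test_closed_form(self):
        assert beer_lambert_mean(0.5, 7.6) == pytest.approx(1 - math.exp(-3.8))

    def test_negative_lai_rejected(self):
        with pytest.raises(DomainError):
            beer_lambert_mean(0.5, -1.0)

    @given(st.floats(0.01, 2.0), st.floats(0.0, 20.0))
    def test_bounded(self, k, lai):
        v = beer_lambert_mean(k, lai)
        assert 0.0 <= v < 1.0

    @given(st.floats(0.05, 2.0))
    def test_monotone_in_lai(self, k):
        grid = np.linspace(0, 10, 50)
        v = beer_lambert_mean(k, grid)
        assert np.all(np.diff(v) > 0)


class TestSse:
    def test_zero_residual_fixed_point(self, noiseless_dataset):
        assert sse([0.5], noiseless_dataset) == pytest.approx(0.0, abs=1e-20)

    def test_single_observation_near_zero(self):
        d = _single([2.0], [0.6321])
        assert sse([0.5], d) == pytest.approx(0.0, abs=1e-7)

    def test_residual_arithmetic(self):
        d = _single([2.0], [0.6321])
        assert sse([0.0], d) == pytest.approx(0.6321**2)

    def test_length_mismatch(self, noiseless_dataset):
        with pytest.raises(ConfigurationError):
            sse([0.5, 0.6], noiseless_dataset)


class TestFitLse:
    def test_noiseless_fixed_point(self, noiseless_dataset):
        fit = fit_lse(noiseless_dataset)
        assert fit.k_estimates["A"] == pytest.approx(0.5, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)
        assert fit.converged

    def test_no_uncertainty_by_construction(self, noiseless_dataset):
        fit = fit_lse(noiseless_dataset)
        assert fit.k_se is None
        assert fit.k_interval is None
        assert fit.dispersion_estimate is None
        assert fit.loglik is None

    def test_matches_grid_search_oracle(self):
        cfg = SyntheticConfig(
            true_k={"A": 0.55}, true_dispersion=12.0, n_per_genotype=30, seed=42
        )
        d = simulate_dataset(cfg)
        lai, y, _ = d.to_arrays()
        step = 1e-4
        grid = np.arange(0.01, 2.0 + step / 2, step)
        losses = ((y[None, :] - (1 - np.exp(-grid[:, None] * lai[None, :]))) ** 2).sum(
            axis=1
        )
        k_grid = grid[np.argmin(losses)]
        fit = fit_lse(d)
        assert abs(fit.k_estimates["A"] - k_grid) <= step

    def test_empty_dataset(self):
        with pytest.raises(ValidationError, match="empty"):
            fit_lse(Dataset())


class TestNormalLoglik:
    def test_observation_at_mean(self):
        d = _single([2.0], [1 - math.exp(-1.0)])
        assert normal_loglik([0.5], 1.0, d) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_additivity(self):
        one = _single([2.0], [0.55])
        two = _single([2.0, 2.0], [0.55, 0.55])
        assert normal_loglik([0.5], 0.1, two) == pytest.approx(
            2 * normal_loglik([0.5], 0.1, one)
        )

    def test_density_sum_oracle(self):
        d = _single([1.0, 2.5, 4.0], [0.3, 0.8, 0.9])
        mu = [1 - math.exp(-0.45 * a) for a in (1.0, 2.5, 4.0)]
        expected = sum(
            stats.norm.logpdf(y, m, math.sqrt(0.02))
            for y, m in zip((0.3, 0.8, 0.9), mu)
        )
        assert normal_loglik([0.45], 0.02, d) == pytest.approx(expected)

    def test_domain(self):
        d = _single([2.0], [0.5])
        with pytest.raises(DomainError):
            normal_loglik([0.5], 0.0, d)


class TestFitMleNormal:
    def test_equals_lse_point_estimates(self, paper_like_dataset):
        lse = fit_lse(paper_like_dataset)
        mle = fit_mle_normal(paper_like_dataset)
        for g in lse.k_estimates:
            assert abs(lse.k_estimates[g] - mle.k_estimates[g]) < 1e-4

    def test_variance_is_sse_over_n(self, paper_like_dataset):
        mle = fit_mle_normal(paper_like_dataset)
        genotypes = paper_like_dataset.genotypes
        rss = sse(mle.k_array(genotypes), paper_like_dataset)
        assert mle.dispersion_estimate == pytest.approx(
            rss / paper_like_dataset.n_obs, rel=1e-5
        )

    def test_ci_width_shrinks_with_noise(self):
        widths = []
        for sigma in (0.05, 0.01):
            cfg = SyntheticConfig(
                true_k={"A": 0.5},
                true_dispersion=sigma**2,
                noise_family="normal",
                n_per_genotype=60,
                seed=3,
            )
            fit = fit_mle_normal(simulate_dataset(cfg))
            lo, hi = fit.k_interval["A"]
            widths.append(hi - lo)
            assert lo < fit.k_estimates["A"] < hi
        assert widths[1] < widths[0]
        assert abs(fit.k_estimates["A"] - 0.5) < 0.01

    def test_wald_interval_construction(self, paper_like_dataset):
        fit = fit_mle_normal(paper_like_dataset)
        for g, (lo, hi) in fit.k_interval.items():
            assert lo == pytest.approx(fit.k_estimates[g] - 1.959964 * fit.k_se[g])
            assert hi == pytest.approx(fit.k_estimates[g] + 1.959964 * fit.k_se[g])


class TestBetaLoglik:
    def test_uniform_special_case(self):
        # mu=0.5, kappa=2 -> beta(1,1): log-density 0 anywhere in (0,1)
        lai = -math.log(0.5) / 0.5  # mean exactly 0.5 at k=0.5
        for y in (0.1, 0.5, 0.93):
            d = _single([lai], [y])
            assert beta_loglik([0.5], 2.0, d) == pytest.approx(0.0, abs=1e-12)

    def test_log_gamma_oracle(self):
        d = _single([2.0], [0.6321])
        mu = 1 - math.exp(-1.0)
        a, b = mu * 12.0, (1 - mu) * 12.0
        expected = (
            math.lgamma(a + b)
            - math.lgamma(a)
            - math.lgamma(b)
            + (a - 1) * math.log(0.6321)
            + (b - 1) * math.log(1 - 0.6321)
        )
        assert beta_loglik([0.5], 12.0, d) == pytest.approx(expected)

    def test_additivity(self):
        one = _single([2.0], [0.55])
        two = _single([2.0, 2.0], [0.55, 0.55])
        assert beta_loglik([0.5], 9.0, two) == pytest.approx(
            2 * beta_loglik([0.5], 9.0, one)
        )

    def test_domain_errors(self):
        d = Dataset.from_observations([CanopyObservation("A", 2.0, 1.0)])
        with pytest.raises(DomainError):
            beta_loglik([0.5], 12.0, d)
        with pytest.raises(DomainError):
            beta_loglik([0.5], 0.0, _single([2.0], [0.5]))


class TestFitMleBeta:
    def test_recovery(self):
        cfg = SyntheticConfig(
            true_k={"A": 0.5}, true_dispersion=12.0, n_per_genotype=300, seed=21
        )
        fit = fit_mle_beta(simulate_dataset(cfg))
        assert abs(fit.k_estimates["A"] - 0.5) < 0.05
        assert fit.converged
        assert fit.dispersion_estimate > 0
        lo, hi = fit.k_interval["A"]
        assert lo < fit.k_estimates["A"] < hi

    def test_boundary_fpari_rejected(self):
        d = Dataset.from_observations(
            [
                CanopyObservation("A", 1.0, 0.4),
                CanopyObservation("A", 2.0, 1.0),
            ]
        )
        with pytest.raises(DomainError):
            fit_mle_beta(d)

    def test_per_genotype_dispersion_flag(self, paper_like_dataset):
        cfg = OptimizerConfig(n_starts=2, shared_dispersion=False)
        fit = fit_mle_beta(paper_like_dataset, cfg)
        assert set(fit.k_estimates) == set(paper_like_dataset.genotype_index)
        per = fit.config_echo["dispersion_per_genotype"]
        assert len(per) == 7


class TestFitLogtlm:
    def test_exact_transform_inversion(self):
        d = _single([1.0, 2.0], [1 - math.exp(-0.5), 1 - math.exp(-1.0)])
        fit = fit_logtlm(d)
        # -(1*(-0.5) + 2*(-1)) / (1 + 4) = 0.5 exactly
        assert fit.k_estimates["A"] == pytest.approx(0.5, abs=1e-15)

    def test_normal_equation_oracle(self):
        lai = [1.0, 2.0, 3.5, 5.0]
        y = [0.35, 0.62, 0.81, 0.93]
        d = _single(lai, y)
        z = [math.log(1 - v) for v in y]
        slope = sum(a * b for a, b in zip(lai, z)) / sum(a * a for a in lai)
        fit = fit_logtlm(d)
        assert fit.k_estimates["A"] == pytest.approx(-slope)
        # SE from through-origin theory
        resid = [b - slope * a for a, b in zip(lai, z)]
        s2 = sum(r * r for r in resid) / (len(lai) - 1)
        se = math.sqrt(s2 / sum(a * a for a in lai))
        assert fit.k_se["A"] == pytest.approx(se)

    def test_single_observation_errors(self):
        d = Dataset.from_arrays(["A", "B", "B"], [1, 2, 3], [0.3, 0.5, 0.7])
        with pytest.raises(ValidationError, match="'A'"):
            fit_logtlm(d)

    def test_fpari_one_rejected(self):
        d = Dataset.from_arrays(["A", "A"], [1, 2], [0.3, 1.0])
        with pytest.raises(DomainError):
            fit_logtlm(d)


class TestLogPosterior:
    def test_outside_prior_support(self):
        d = _single([2.0], [0.5])
        assert log_posterior([2.5], 12.0, d) == -np.inf
        assert log_posterior([0.5], -1.0, d) == -np.inf

    def test_empty_dataset_prior_only_mode(self):
        d = Dataset(observations=[], genotype_index={"A": 1})
        kappas = np.linspace(5, 20, 1501)
        values = [log_posterior([0.7], kp, d) for kp in kappas]
        # gamma(24, 2) shape-rate mode: (24 - 1) / 2 = 11.5
        assert kappas[int(np.argmax(values))] == pytest.approx(11.5, abs=0.02)

    def test_flat_prior_structure(self):
        d = _single([1.0, 3.0], [0.4, 0.8])
        priors = PriorSpec()
        delta_post = log_posterior([0.6], 12.0, d, priors) - log_posterior(
            [0.4], 12.0, d, priors
        )
        delta_ll = beta_loglik([0.6], 12.0, d) - beta_loglik([0.4], 12.0, d)
        assert delta_post == pytest.approx(delta_ll)


class TestNumericHessian:
    def test_quadratic_recovery(self):
        A = np.array([[3.0, 0.7], [0.7, 2.0]])
        f = lambda x: 0.5 * x @ A @ x
        H = numeric_hessian(f, np.array([0.3, -0.2]))
        assert np.allclose(H, A, rtol=1e-4)

    def test_one_dimensional_parabola(self):
        H = numeric_hessian(lambda x: (x[0] - 0.5) ** 2, np.array([0.5]))
        assert H[0, 0] == pytest.approx(2.0, rel=1e-6)

    def test_symmetry(self):
        f = lambda x: x[0] ** 2 * x[1] + math.sin(x[1]) * x[0]
        H = numeric_hessian(f, np.array([0.4, 0.9]))
        assert np.array_equal(H, H.T)

    def test_non_finite_raises(self):
        f = lambda x: math.inf if x[0] > 1.0 else x[0] ** 2
        with pytest.raises(NumericError):
            numeric_hessian(f, np.array([1.0]), step=0.1)

    def test_se_shrinks_at_root_n_rate(self):
        ses = {}
        for n in (100, 400):
            cfg = SyntheticConfig(
                true_k={"A": 0.5},
                true_dispersion=0.03**2,
                noise_family="normal",
                n_per_genotype=n,
                seed=17,
            )
            fit = fit_mle_normal(simulate_dataset(cfg))
            ses[n] = fit.k_se["A"]
        assert ses[400] / ses[100] == pytest.approx(0.5, rel=0.25)


class TestMetropolis:
    def test_burnin_validation(self):
        with pytest.raises(ConfigurationError):
            MCMCConfig(n_iter=100, n_burnin=100)

    def test_reproducible(self):
        d = Dataset(observations=[], genotype_index={"A": 1})
        mcmc = MCMCConfig(n_iter=2000, n_burnin=500, seed=4)
        s1 = run_metropolis(d, mcmc=mcmc)
        s2 = run_metropolis(d, mcmc=mcmc)
        assert np.array_equal(s1.draws, s2.draws)
        assert s1.acceptance_rate == s2.acceptance_rate

    def test_prior_recovery_on_empty_dataset(self):
        import arviz

        d = Dataset(observations=[], genotype_index={"A": 1})
        s = run_metropolis(d, mcmc=MCMCConfig(n_iter=12000, n_burnin=2000, seed=5))
        k = s.draws[:, 0]
        ess = float(arviz.ess(arviz.convert_to_dataset(k[None, :]))["x"])
        mc_se = k.std() / math.sqrt(ess)
        # uniform(0, 2) has mean 1 and sd 1/sqrt(3)
        assert abs(k.mean() - 1.0) < 3 * mc_se
        assert np.all((k > 0) & (k < 2))
        assert np.all(s.draws[:, 1] > 0)

    def test_draws_within_prior_support(self, paper_like_dataset):
        s = run_metropolis(
            paper_like_dataset, mcmc=MCMCConfig(n_iter=800, n_burnin=200, seed=6)
        )
        k = s.draws[:, :-1]
        assert np.all((k > 0) & (k < 2))
        assert 0 < s.acceptance_rate < 1


class TestSummarizePosterior:
    def _samples(self, draws):
        from canopyk import PosteriorSamples

        return PosteriorSamples(
            draws=np.asarray(draws, dtype=float),
            genotypes=["A"],
            n_burnin=0,
            n_iter=len(draws),
            thin=1,
            acceptance_rate=0.3,
            seed=0,
        )

    def test_degenerate_chain(self):
        s = self._samples([[0.5, 12.0]] * 10)
        fit = summarize_posterior(s)
        assert fit.k_estimates["A"] == 0.5
        lo, hi = fit.k_interval["A"]
        assert lo == hi == 0.5

    def test_mean_arithmetic(self):
        s = self._samples([[0.4, 10.0], [0.5, 12.0], [0.6, 14.0]])
        fit = summarize_posterior(s)
        assert fit.k_estimates["A"] == pytest.approx(0.5)
        assert fit.dispersion_estimate == pytest.approx(12.0)

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        draws = np.column_stack([rng.normal(0.5, 0.05, 501), rng.gamma(24, 0.5, 501)])
        s = self._samples(draws)
        fit = summarize_posterior(s)
        x = np.sort(draws[:, 0])
        # order-statistic interpolation at p = 0.025 / 0.975 (linear rule)
        def q(p):
            h = p * (len(x) - 1)
            lo = int(math.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        lo, hi = fit.k_interval["A"]
        assert lo == pytest.approx(q(0.025))
        assert hi == pytest.approx(q(0.975))

    def test_zero_draws_error(self):
        s = self._samples(np.empty((0, 2)))
        with pytest.raises(ValidationError):
            summarize_posterior(s)


class TestNoiselessExactness:
    def test_all_methods_recover_truth(self):
        d = make_noiseless_dataset({"A": 0.5, "B": 0.65})
        assert fit_logtlm(d).k_estimates["A"] == pytest.approx(0.5, abs=1e-12)
        assert fit_lse(d).k_estimates["B"] == pytest.approx(0.65, abs=1e-6)
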