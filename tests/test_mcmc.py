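import numpy as np
import pytest
from scipy import stats

import stagehmm as sh
from stagehmm.covariates import ParameterLayout

CONST = sh.ModelStructure("constant", "full_stage", "constant")
PRIORS = sh.PriorSpec(egg_survival=(8.8, 1.2), egg_hatch=(7, 3), pupation=(3.5, 6.5))


def natural_vector(**overrides):
    layout = ParameterLayout(CONST)
    pv = sh.ParameterVector(
        b0=np.zeros(5),
        a0=np.zeros(7),
        p_live=np.full(6, 0.5),
        p_dead=np.full(5, 0.5),
        egg_survival=0.5,
        egg_hatch=0.5,
        pupation=0.5,
    )
    x = layout.natural(pv)
    names = list(layout.names)
    for name, value in overrides.items():
        x[names.index(name)] = value
    return layout, x


class TestLogPrior:
    def test_coefficient_contribution_is_normal_density(self):
        _, x0 = natural_vector()
        _, x1 = natural_vector(**{"b0[I1]": 1.0})
        delta = sh.log_prior(x1, PRIORS, CONST) - sh.log_prior(x0, PRIORS, CONST)
        expected = stats.norm.logpdf(1.0, 0, 100) - stats.norm.logpdf(0.0, 0, 100)
        assert delta == pytest.approx(expected, abs=1e-12)
        # and the sd-100 normal at zero contributes -log(100) - log(2 pi)/2
        assert stats.norm.logpdf(0.0, 0, 100) == pytest.approx(-np.log(100) - 0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_uniform_detection_contributes_nothing(self):
        _, x0 = natural_vector()
        _, x1 = natural_vector(**{"p_live[I2]": 0.87})
        assert sh.log_prior(x0, PRIORS, CONST) == pytest.approx(
            sh.log_prior(x1, PRIORS, CONST), abs=1e-12
        )

    def test_probability_outside_support_is_impossible(self):
        _, x = natural_vector(**{"p_dead[I3]": 1.2})
        assert sh.log_prior(x, PRIORS, CONST) == -np.inf

    def test_beta_terms_use_the_informative_priors(self):
        _, x0 = natural_vector()
        _, x1 = natural_vector(egg_hatch=0.7)
        delta = sh.log_prior(x1, PRIORS, CONST) - sh.log_prior(x0, PRIORS, CONST)
        expected = stats.beta.logpdf(0.7, 7, 3) - stats.beta.logpdf(0.5, 7, 3)
        assert delta == pytest.approx(expected, abs=1e-12)


class TestGenericSampler:
    def test_binomial_posterior_matches_beta_closed_form(self):
        # 37 detections of 50 trials, uniform prior -> Beta(38, 14).
        k, n = 37, 50

        def logpost(x):
            p = x[0]
            if not 0.0 < p < 1.0:
                return -np.inf, 0.0
            return k * np.log(p) + (n - k) * np.log1p(-p), 0.0

        rng = np.random.default_rng(7)
        draws, _, rates = sh.adaptive_metropolis(
            logpost, np.array([0.5]), [np.array([0])], 1500, 6000, rng, target_accept=0.44
        )
        post_mean = draws.mean()
        exact = 38 / 52
        mc_err = 3 * np.sqrt(stats.beta.var(38, 14) / 400)  # generous ESS allowance
        assert abs(post_mean - exact) < mc_err

    def test_two_dim_normal_target_matches_direct_sampling(self):
        # Detailed-balance smoke test: QQ/KS agreement with direct draws.
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        prec = np.linalg.inv(cov)

        def logpost(x):
            return -0.5 * x @ prec @ x, 0.0

        rng = np.random.default_rng(13)
        draws, _, _ = sh.adaptive_metropolis(
            logpost, np.zeros(2), [np.array([0]), np.array([1])], 2000, 5000, rng
        )
        direct = np.random.default_rng(14).multivariate_normal(np.zeros(2), cov, 5000)
        thinned = draws[::5]
        for j in range(2):
            p = stats.ks_2samp(thinned[:, j], direct[:, j]).pvalue
            assert p > 0.01

    def test_non_finite_start_raises(self):
        def logpost(x):
            return -np.inf, 0.0

        with pytest.raises(ValueError, match="re-initialize"):
            sh.adaptive_metropolis(
                logpost, np.zeros(1), [np.array([0])], 10, 10, np.random.default_rng(0)
            )


class TestRunMcmc:
    @pytest.fixture(scope="class")
    def short_fit(self, small_cohort):
        cfg, histories, _, truth = small_cohort
        priors = sh.matched_priors(cfg.params)
        settings = sh.MCMCSettings(chains=2, burn_in=600, samples=600, seed=5)
        return cfg, histories, priors, settings, sh.run_mcmc(
            histories, cfg.structure, priors, settings
        )

    def test_seeded_chains_are_bit_identical(self, short_fit):
        cfg, histories, priors, settings, sample = short_fit
        again = sh.run_mcmc(histories, cfg.structure, priors, settings)
        assert np.array_equal(sample.draws, again.draws)
        assert np.array_equal(sample.deviance, again.deviance)

    def test_output_shapes_and_scales(self, short_fit):
        cfg, _, _, settings, sample = short_fit
        layout = ParameterLayout(cfg.structure)
        assert sample.draws.shape == (2, 600, layout.size)
        assert sample.deviance.shape == (2, 600)
        prob = layout.prob_mask
        flat = sample.flat()
        assert np.all((flat[:, prob] >= 0) & (flat[:, prob] <= 1))
        assert np.all(np.isfinite(sample.deviance))
        assert sample.mean_deviance > 0

    def test_acceptance_rates_are_tuned(self, short_fit):
        *_, sample = short_fit
        assert np.all(sample.acceptance >= 0.1)
        assert np.all(sample.acceptance <= 0.6)

    def test_deviance_draws_match_evaluator(self, short_fit):
        cfg, histories, _, _, sample = short_fit
        layout = ParameterLayout(cfg.structure)
        dl = sh.DatasetLikelihood(histories, cfg.structure)
        pv = layout.from_natural(sample.draws[0, -1])
        assert sample.deviance[0, -1] == pytest.approx(dl.deviance(pv), rel=1e-10)

    def test_long_dataframe_round_trips(self, short_fit):
        *_, sample = short_fit
        df = sample.to_dataframe()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        back = df[(df.chain == 1) & (df.parameter == sample.names[0])]["value"].to_numpy()
        np.testing.assert_array_equal(back, sample.draws[1, :, 0])


class TestGelmanRubin:
    def test_identical_chains_hit_the_floor(self):
        rng = np.random.default_rng(3)
        one = rng.normal(size=(500, 2))
        gr = sh.gelman_rubin(np.stack([one, one]))
        n = 500
        np.testing.assert_allclose(gr["psrf"], np.sqrt((n - 1) / n), atol=1e-12)

    def test_iid_chains_are_close_to_one(self):
        rng = np.random.default_rng(21)
        chains = rng.normal(size=(2, 1000, 1))
        gr = sh.gelman_rubin(chains)
        assert 0.99 <= gr["psrf"][0] <= 1.05
        assert 0.99 <= gr["multivariate_psrf"] <= 1.06

    def test_disjoint_chains_blow_up(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.01, size=(400, 1))
        b = rng.normal(10, 0.01, size=(400, 1))
        gr = sh.gelman_rubin(np.stack([a, b]))
        assert gr["psrf"][0] > 5

    def test_zero_within_variance_is_flagged_undefined(self):
        chains = np.zeros((2, 100, 1))
        chains[1] += 1.0
        gr = sh.gelman_rubin(chains)
        assert np.isnan(gr["psrf"][0])

    def test_input_requirements(self):
        with pytest.raises(ValueError):
            sh.gelman_rubin(np.zeros((1, 100, 2)))
        with pytest.raises(ValueError):
            sh.gelman_rubin(np.zeros((2, 5, 2)))

    def test_agrees_with_arviz_on_stationary_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(31)
        chains = np.empty((3, 800, 2))
        for c in range(3):
            x = np.zeros(2)
            for t in range(800):
                x = 0.5 * x + rng.normal(size=2)
                chains[c, t] = x
        ours = sh.gelman_rubin(chains)["psrf"]
        theirs = arviz.rhat(arviz.convert_to_dataset(chains)).x.values
        np.testing.assert_allclose(ours, theirs, atol=0.05)


class TestMultivariateEss:
    def test_iid_draws_have_full_efficiency(self):
        rng = np.random.default_rng(17)
        draws = rng.normal(size=(4000, 1))
        assert 0.8 <= sh.multivariate_ess(draws) / 4000 <= 1.2

    def test_autocorrelated_chain_is_heavily_discounted(self):
        rng = np.random.default_rng(19)
        n = 5000
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = 0.9 * x[t - 1] + rng.normal()
        assert sh.multivariate_ess(x[:, np.newaxis]) / n < 0.2

    def test_duplicated_coordinate_is_singular(self):
        rng = np.random.default_rng(23)
        col = rng.normal(size=(2000, 1))
        with pytest.raises(ValueError, match="singular"):
            sh.multivariate_ess(np.hstack([col, col]))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            sh.multivariate_ess(np.zeros((20, 5)))


class TestPosteriorSummary:
    def _sample(self, draws):
        draws = np.asarray(draws, dtype=float).reshape(1, -1, 1)
        return sh.PosteriorSample(
            structure=CONST,
            names=("b0[I1]",),
            draws=draws,
            deviance=np.zeros(draws.shape[:2]),
            acceptance=np.full((1, 1), 0.4),
            block_names=("b0[I1]",),
            settings=sh.MCMCSettings(chains=1, burn_in=0, samples=draws.shape[1], seed=0),
        )

    def test_constant_chain(self):
        df = sh.posterior_summary(self._sample([3.0] * 50))
        row = df.loc["b0[I1]"]
        assert row["mean"] == 3.0 and row["sd"] == 0.0
        assert row["q2.5"] == row["q97.5"] == 3.0

    def test_symmetric_two_point_chain(self):
        df = sh.posterior_summary(self._sample([-1.0, 1.0] * 100))
        assert df.loc["b0[I1]", "mean"] == pytest.approx(0.0)

    def test_standard_normal_interval(self):
        draws = np.random.default_rng(29).normal(size=20_000)
        df = sh.posterior_summary(self._sample(draws))
        assert df.loc["b0[I1]", "q2.5"] == pytest.approx(-1.96, abs=0.06)
        assert df.loc["b0[I1]", "q97.5"] == pytest.approx(1.96, abs=0.06)
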