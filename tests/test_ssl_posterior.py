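import numpy as np
import pytest
from scipy import stats

from pride import (
    InteractionDesign,
    MCMCConfig,
    ModelState,
    build_interaction_design,
    log_unnormalized_posterior,
    sample_posterior,
    summarize_posterior,
)
from pride.screening import ScreenSet

from _oracles import inclusion_prob_quadrature


def _screenset(*pairs):
    return ScreenSet(pairs=tuple(pairs), deltas=tuple(0.5 for _ in pairs))


class TestDesign:
    def test_columns_are_products(self, toy_standardized):
        design = build_interaction_design(toy_standardized, _screenset((0, 1), (1, 2)))
        x = toy_standardized.values
        np.testing.assert_array_equal(design.Z[:, 0], x[:, 0] * x[:, 1])
        np.testing.assert_array_equal(design.Z[:, 1], x[:, 1] * x[:, 2])

    def test_empty_screen_rejected(self, toy_standardized):
        with pytest.raises(ValueError, match="empty screen"):
            build_interaction_design(toy_standardized, ScreenSet(pairs=(), deltas=()))

    def test_unknown_gene_rejected(self, toy_standardized):
        with pytest.raises(ValueError, match="outside"):
            build_interaction_design(toy_standardized, _screenset((0, 9)))


class TestLogPosterior:
    def test_null_state_closed_form(self, default_prior):
        """alpha0 = beta = 0: likelihood is N log(1/2); the slab log-density
        at 0 is log(tau1/2) = 0 for tau1 = 2; the spike is log(tau0/2)."""
        n = 6
        design = InteractionDesign(Z=np.ones((n, 1)), pair_index=((0, 1),))
        y = np.array([0, 1, 0, 1, 0, 1])
        lp_alpha = stats.norm(0, default_prior.intercept_sd).logpdf(0.0)

        slab = log_unnormalized_posterior(
            ModelState(0.0, np.zeros(1), np.ones(1, dtype=int)), design, y, default_prior
        )
        assert slab == pytest.approx(
            n * np.log(0.5) + 0.0 + np.log(default_prior.theta) + lp_alpha
        )

        spike = log_unnormalized_posterior(
            ModelState(0.0, np.zeros(1), np.zeros(1, dtype=int)), design, y, default_prior
        )
        assert spike == pytest.approx(
            n * np.log(0.5) + np.log(10.0) + np.log(1 - default_prior.theta) + lp_alpha
        )

    def test_non_finite_state_rejected(self, default_prior):
        design = InteractionDesign(Z=np.ones((2, 1)), pair_index=((0, 1),))
        with pytest.raises(ValueError, match="non-finite"):
            log_unnormalized_posterior(
                ModelState(np.inf, np.zeros(1), np.ones(1, dtype=int)),
                design,
                np.array([0, 1]),
                default_prior,
            )


def _empty_design(s=1):
    return InteractionDesign(
        Z=np.zeros((0, s)), pair_index=tuple((0, i + 1) for i in range(s))
    )


class TestSampler:
    def test_prior_recovery_gamma(self, default_prior):
        """With no data the gamma draws must reproduce the prior rate theta."""
        draws = sample_posterior(
            _empty_design(),
            np.zeros(0),
            default_prior,
            MCMCConfig(iterations=7000, burn_in=1000, chains=2, seed=11),
            diagnostics=False,
        )
        import arviz as az

        mean_gamma = draws.gamma_flat.mean()
        # the draws autocorrelate (ESS fraction ~0.25), so the Monte-Carlo SE
        # uses the effective, not nominal, sample size
        ess = float(az.ess(draws.gamma[:, :, 0].astype(float)))
        mc_se = np.sqrt(mean_gamma * (1 - mean_gamma) / ess)
        assert abs(mean_gamma - default_prior.theta) < 3 * mc_se

    def test_prior_recovery_beta_mixture(self, default_prior):
        """Beta draws at N=0 follow the two-component Laplace mixture."""
        draws = sample_posterior(
            _empty_design(),
            np.zeros(0),
            default_prior,
            MCMCConfig(iterations=11000, burn_in=1000, chains=2, seed=12),
            diagnostics=False,
        )
        b = np.sort(draws.beta_flat[:, 0])

        def mix_cdf(x):
            return default_prior.theta * stats.laplace(scale=1 / 2).cdf(x) + (
                1 - default_prior.theta
            ) * stats.laplace(scale=1 / 20).cdf(x)

        ks = np.max(np.abs(mix_cdf(b) - np.arange(1, b.size + 1) / b.size))
        assert ks < 0.03  # generous vs the 0.012 iid 99% band, draws autocorrelate

    def test_seeded_determinism(self, default_prior):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(15)
        y = (rng.random(15) < 0.5).astype(int)
        design = InteractionDesign(Z=z[:, None], pair_index=((0, 1),))
        cfg = MCMCConfig(iterations=500, burn_in=100, chains=2, seed=99)
        a = sample_posterior(design, y, default_prior, cfg, diagnostics=False)
        b = sample_posterior(design, y, default_prior, cfg, diagnostics=False)
        np.testing.assert_array_equal(a.alpha0, b.alpha0)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.gamma, b.gamma)

    @pytest.mark.parametrize("s,seed,coef", [(1, 42, (1.2,)), (2, 43, (0.9, -0.2))])
    def test_matches_quadrature_oracle(self, default_prior, s, seed, coef):
        """Headline correctness: MCMC inclusion probabilities agree with
        enumeration over gamma + numerical integration over (alpha0, beta)."""
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((20, s))
        y = (rng.random(20) < 1 / (1 + np.exp(-Z @ np.array(coef)))).astype(int)
        oracle = inclusion_prob_quadrature(Z, y, default_prior)
        design = InteractionDesign(Z=Z, pair_index=tuple((0, i + 1) for i in range(s)))
        draws = sample_posterior(
            design,
            y,
            default_prior,
            MCMCConfig(iterations=16000, burn_in=2000, chains=2, seed=5),
            diagnostics=False,
        )
        summary = summarize_posterior(draws)
        np.testing.assert_allclose(summary.inclusion_prob, oracle, atol=0.02)

    def test_label_flip_symmetry(self, default_prior):
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((30, 2))
        y = (rng.random(30) < 1 / (1 + np.exp(-(0.5 + Z[:, 0])))).astype(int)
        design = InteractionDesign(Z=Z, pair_index=((0, 1), (0, 2)))
        cfg = MCMCConfig(iterations=8000, burn_in=2000, chains=2, seed=13)
        s_pos = summarize_posterior(
            sample_posterior(design, y, default_prior, cfg, diagnostics=False)
        )
        s_neg = summarize_posterior(
            sample_posterior(design, 1 - y, default_prior, cfg, diagnostics=False)
        )
        np.testing.assert_allclose(s_neg.beta_mean, -s_pos.beta_mean, atol=0.08)
        np.testing.assert_allclose(s_neg.inclusion_prob, s_pos.inclusion_prob, atol=0.05)

    def test_true_interactions_outrank_null(self, default_prior):
        """At N=500 pairs with real effects get higher inclusion probability."""
        rng = np.random.default_rng(21)
        s, n_true = 12, 3
        Z = rng.standard_normal((500, s))
        beta = np.zeros(s)
        beta[:n_true] = 1.5
        y = (rng.random(500) < 1 / (1 + np.exp(-Z @ beta))).astype(int)
        design = InteractionDesign(Z=Z, pair_index=tuple((0, i + 1) for i in range(s)))
        draws = sample_posterior(
            design,
            y,
            default_prior,
            MCMCConfig(iterations=2000, burn_in=1000, chains=1, seed=6),
            diagnostics=False,
        )
        summary = summarize_posterior(draws)
        true_mean = summary.inclusion_prob[:n_true].mean()
        null_mean = summary.inclusion_prob[n_true:].mean()
        assert true_mean > null_mean + 0.2
        p = stats.mannwhitneyu(
            summary.inclusion_prob[:n_true],
            summary.inclusion_prob[n_true:],
            alternative="greater",
        ).pvalue
        assert p < 0.05

    def test_single_class_warns(self, default_prior):
        design = InteractionDesign(Z=np.ones((4, 1)), pair_index=((0, 1),))
        with pytest.warns(UserWarning, match="single class"):
            sample_posterior(
                design,
                np.ones(4, dtype=int),
                default_prior,
                MCMCConfig(iterations=200, burn_in=100, chains=1, seed=1),
                diagnostics=False,
            )


class TestSummaries:
    def _draws(self, alpha0, beta, gamma):
        from pride.ssl_posterior import PosteriorDraws

        return PosteriorDraws(
            alpha0=alpha0[None, :],
            beta=beta[None, :, :],
            gamma=gamma[None, :, :],
            pair_index=tuple((0, i + 1) for i in range(beta.shape[1])),
            config=MCMCConfig(iterations=beta.shape[0] + 1, burn_in=0, seed=0),
        )

    def test_degenerate_gamma_and_symmetric_beta(self):
        beta = np.array([[-1.0], [0.0], [1.0]])
        gamma = np.ones((3, 1), dtype=np.int8)
        with pytest.warns(UserWarning, match="retained draws"):
            summary = summarize_posterior(self._draws(np.zeros(3), beta, gamma))
        assert summary.inclusion_prob[0] == 1.0
        assert summary.beta_mean[0] == 0.0

    def test_quantiles_match_sampling_theory(self):
        rng = np.random.default_rng(17)
        t = 2000
        b = rng.laplace(scale=0.5, size=(t, 1))
        summary = summarize_posterior(
            self._draws(np.zeros(t), b, np.ones((t, 1), dtype=np.int8))
        )
        true_q = stats.laplace(scale=0.5).ppf([0.025, 0.5, 0.975])
        # order-statistic tolerance: ~3 SE of the empirical quantile
        for est, q, p in zip(summary.beta_quantiles[:, 0], true_q, [0.025, 0.5, 0.975]):
            se = np.sqrt(p * (1 - p) / t) / stats.laplace(scale=0.5).pdf(q)
            assert abs(est - q) < 3.5 * se
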