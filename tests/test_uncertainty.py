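import numpy as np
import pytest

from spatialinfo import SamplerConfig
from spatialinfo.uncertainty import (
    GeneExpressionSampler,
    default_size_factors,
    sample_expression_dm,
    sample_expression_gaussian,
    sample_expression_gp,
)


class TestGammaPoisson:
    def test_posterior_mean(self, rng):
        # conjugate update: count 3, a0=b0=1, size factor 1 -> mean (1+3)/(1+1)=2
        cfg = SamplerConfig(model="gamma_poisson", prior_shape=1.0, prior_rate=1.0,
                            transform="identity")
        counts = np.full((10_000, 1), 3.0)
        draws = sample_expression_gp(counts, np.ones(10_000), cfg, rng)
        assert draws.mean() == pytest.approx(2.0, abs=0.05)

    def test_zero_count_vague_prior_near_zero(self, rng):
        cfg = SamplerConfig(model="gamma_poisson", prior_shape=1e-8, prior_rate=1.0,
                            transform="identity")
        draws = sample_expression_gp(np.zeros((1000, 1)), np.ones(1000), cfg, rng)
        assert np.all(draws < 1e-3)

    def test_seed_determinism(self):
        cfg = SamplerConfig(model="gamma_poisson")
        counts = np.arange(12.0).reshape(4, 3)
        a = sample_expression_gp(counts, np.ones(4), cfg, np.random.default_rng(5))
        b = sample_expression_gp(counts, np.ones(4), cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_non_integral_counts_rejected(self, rng):
        cfg = SamplerConfig(model="gamma_poisson")
        with pytest.raises(ValueError, match="integral"):
            sample_expression_gp(np.array([[1.5]]), np.ones(1), cfg, rng)

    def test_convergence_rate_in_draw_count(self, rng):
        # MC error of the sample mean shrinks ~ m^{-1/2}
        cfg = SamplerConfig(model="gamma_poisson", prior_shape=1.0, prior_rate=1.0,
                            transform="identity")
        errs = []
        for m in (100, 10_000):
            draws = sample_expression_gp(np.full((m, 1), 3.0), np.ones(m), cfg, rng)
            errs.append(abs(draws.mean() - 2.0))
        assert errs[1] < errs[0]


class TestDirichletMultinomial:
    def test_posterior_mean_proportion(self, rng):
        # counts (5,5), a0d=1: posterior Dir(6,6), mean proportion 0.5
        cfg = SamplerConfig(model="dirichlet_multinomial", dirichlet_prior=1.0,
                            transform="identity")
        counts = np.tile([5.0, 5.0], (10_000, 1))
        draws = sample_expression_dm(counts, cfg, rng) / 1e4
        assert draws[:, 0].mean() == pytest.approx(0.5, abs=0.01)

    def test_degenerate_concentration(self, rng):
        cfg = SamplerConfig(model="dirichlet_multinomial", dirichlet_prior=1e-9,
                            transform="identity")
        draws = sample_expression_dm(np.tile([10.0, 0, 0], (500, 1)), cfg, rng) / 1e4
        np.testing.assert_allclose(draws[:, 0], 1.0, atol=1e-6)

    def test_rows_on_simplex(self, rng):
        cfg = SamplerConfig(model="dirichlet_multinomial", transform="identity")
        counts = rng.integers(0, 20, (50, 8)).astype(float) + 1
        draws = sample_expression_dm(counts, cfg, rng) / 1e4
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_total_warns(self, rng):
        cfg = SamplerConfig(model="dirichlet_multinomial", transform="identity")
        with pytest.warns(UserWarning, match="zero total"):
            sample_expression_dm(np.zeros((2, 3)), cfg, rng)

    def test_beta_marginal_matches_dirichlet(self):
        # the per-gene sampler uses the Beta marginal of the Dirichlet; the
        # full-matrix sampler is the independent route to the same law
        cfg = SamplerConfig(model="dirichlet_multinomial", dirichlet_prior=0.5,
                            transform="identity")
        counts = np.tile([3.0, 7.0, 0.0], (20_000, 1))
        full = sample_expression_dm(counts, cfg, np.random.default_rng(1)) / 1e4
        sampler = GeneExpressionSampler(
            counts[:, 0], cfg, cell_totals=counts.sum(axis=1), n_genes=3,
            standardize=False,
        )
        marg = sampler.draw(np.random.default_rng(2)) / 1e4
        assert marg.mean() == pytest.approx(full[:, 0].mean(), abs=0.01)
        assert marg.std() == pytest.approx(full[:, 0].std(), abs=0.01)


class TestGaussian:
    def test_sd_limit_recovers_mean(self, rng):
        mean = np.arange(6.0).reshape(2, 3)
        draws = sample_expression_gaussian(mean, np.full((2, 3), 1e-12), rng)
        np.testing.assert_allclose(draws, mean, atol=1e-9)

    def test_sample_sd(self, rng):
        draws = sample_expression_gaussian(np.zeros((10_000, 1)), np.ones((10_000, 1)), rng)
        assert draws.std() == pytest.approx(1.0, abs=0.03)

    def test_missing_sd_error(self, rng):
        with pytest.raises(ValueError):
            sample_expression_gaussian(np.zeros((2, 2)), None, rng)


class TestGeneSampler:
    def test_none_mode_deterministic(self):
        cfg = SamplerConfig(model="none")
        s = GeneExpressionSampler(np.array([0.0, 1, 2, 5]), cfg)
        a = s.draw(np.random.default_rng(1))
        b = s.draw(np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_standardized_output(self, rng):
        cfg = SamplerConfig(model="gamma_poisson")
        s = GeneExpressionSampler(
            np.arange(100.0), cfg, size_factors=np.ones(100)
        )
        x = s.draw(rng)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_gene_detected(self):
        cfg = SamplerConfig(model="none")
        assert GeneExpressionSampler(np.zeros(10), cfg).is_constant()
        assert not GeneExpressionSampler(np.arange(10.0), cfg).is_constant()


def test_default_size_factors_median_one():
    sf = default_size_factors(np.array([100.0, 200.0, 400.0]))
    assert sf[1] == 1.0
    assert np.all(sf > 0)
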