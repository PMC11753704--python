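import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from regfine.model import (
    PriorSettings,
    ResidualVariances,
    averaged_log_bf,
    build_prior_grid,
    config_log_prior,
    config_residual_variance,
    detect_large_effects,
    log_bf,
    score_configurations,
    univariate_residual_variance,
    _anchor_configuration,
)
from regfine.summary_data import GenotypeMatrix, summary_from_individual
from conftest import region_from_z, standardize


def individual_dataset(rng, n=400, m=6, betas=None, rho=0.5):
    """Correlated standardized genotypes + phenotype; exact ML summaries."""
    latent = rng.normal(size=(n, m))
    for j in range(1, m):
        latent[:, j] = rho * latent[:, j - 1] + math.sqrt(1 - rho**2) * latent[:, j]
    g = GenotypeMatrix.from_raw(latent)
    y = np.zeros(n)
    if betas is not None:
        for j, b in betas.items():
            y = y + b * g.g[:, j]
    y = standardize(y + rng.normal(size=n))
    return g, y, summary_from_individual(g, y)


class TestUnivariateResidualVariance:
    @pytest.mark.parametrize("z,n,expected", [
        (0.0, 1000, 1.0),
        (math.sqrt(1000), 1000, 0.5),
    ])
    def test_closed_form(self, z, n, expected):
        assert univariate_residual_variance(z, n) == pytest.approx(expected)

    def test_matches_one_minus_r2_from_ols(self, rng):
        # build data whose univariate regression gives a large z, compare
        # the summary formula with 1 - R^2 computed from the fit itself
        n = 10_000
        x = standardize(rng.normal(size=n))
        y = standardize(0.2 * x + rng.normal(size=n) * 0.98)
        b = float(x @ y / n)
        resid = y - b * x
        sigma2_ml = float(np.mean(resid**2))
        z = b / math.sqrt(sigma2_ml / n)
        assert univariate_residual_variance(z, n) == pytest.approx(sigma2_ml,
                                                                   rel=1e-10)
        assert univariate_residual_variance(20.0, 10_000) == pytest.approx(
            1 / (1 + 400 / 10_000))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            univariate_residual_variance(1.0, 0)


class TestDetectLargeEffects:
    def test_all_null(self):
        region = region_from_z(np.zeros(4), np.eye(4), 9900)
        assert detect_large_effects(region, 0.01) is False

    @pytest.mark.parametrize("zmax,expected", [(10.5, True), (9.0, False)])
    def test_threshold_boundary(self, zmax, expected):
        # brute-force check of 1-(1+z^2/n)^-1 > 0.01 at n=9900
        n = 9900
        region = region_from_z([1.0, zmax, 2.0], np.eye(3), n)
        brute = max(1 - 1 / (1 + z**2 / n) for z in [1.0, zmax, 2.0]) > 0.01
        assert detect_large_effects(region, 0.01) is expected
        assert brute is expected


class TestConfigResidualVariance:
    def test_empty_configuration(self, identity_region):
        resid = ResidualVariances.from_region(identity_region)
        assert config_residual_variance([], identity_region, resid) == 1.0

    def test_single_variant_equals_univariate(self, identity_region):
        resid = ResidualVariances.from_region(identity_region)
        for j in range(identity_region.m):
            got = config_residual_variance([j], identity_region, resid)
            assert got == pytest.approx(resid.per_variant[j], rel=1e-12)

    def test_pair_matches_joint_ols_residual_variance(self, rng):
        g, y, region = individual_dataset(rng, n=800, m=4,
                                          betas={0: 0.4, 2: 0.25})
        resid = ResidualVariances.from_region(region)
        for pair in [(0, 2), (1, 3), (0, 1)]:
            x = g.g[:, list(pair)]
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            sigma2_ols = float(np.mean((y - x @ coef) ** 2))
            got = config_residual_variance(pair, region, resid)
            assert got == pytest.approx(sigma2_ols, abs=1e-6)


class TestLogBF:
    def test_null_configuration_is_zero(self, identity_region):
        resid = ResidualVariances.from_region(identity_region)
        assert log_bf([], identity_region, resid, 0.0025, 1.0) == 0.0

    def test_single_null_variant_closed_form(self):
        # k=1, z=0, sigma2=1, s2=0.0025, n=40000: BF = det(1+n s2)^(-1/2)
        region = region_from_z([0.0], np.eye(1), 40_000)
        resid = ResidualVariances.from_region(region)
        got = log_bf([0], region, resid, 0.0025, 1.0)
        assert got == pytest.approx(-0.5 * math.log(101), rel=1e-12)

    def test_matches_full_gaussian_marginal_likelihood(self, rng):
        """Summary-based BF equals the n-dimensional Gaussian likelihood
        ratio N(y|0, sigma2 I + s2 XX') / N(y|0, I) on the generating data."""
        g, y, region = individual_dataset(rng, n=300, m=5,
                                          betas={1: 0.35, 3: 0.2})
        resid = ResidualVariances.from_region(region)
        log_null = multivariate_normal.logpdf(y, cov=np.eye(300))
        for config in [(1,), (1, 3), (0, 2, 4)]:
            s2 = 0.01
            sigma2 = config_residual_variance(config, region, resid)
            x = g.g[:, list(config)]
            cov = sigma2 * np.eye(300) + s2 * (x @ x.T)
            oracle = multivariate_normal.logpdf(y, cov=cov) - log_null
            got = log_bf(config, region, resid, s2, sigma2)
            assert got == pytest.approx(oracle, rel=1e-6)

    def test_invariant_under_index_order(self, rng):
        _, _, region = individual_dataset(rng, n=200, m=5, betas={0: 0.3})
        resid = ResidualVariances.from_region(region)
        a = log_bf([3, 0, 4], region, resid, 0.0025, 0.9)
        b = log_bf([4, 3, 0], region, resid, 0.0025, 0.9)
        assert a == b

    def test_monotone_in_abs_z_for_single_variant(self):
        n = 10_000
        values = []
        for z in [0.0, 1.0, 3.0, 6.0, 12.0]:
            region = region_from_z([z], np.eye(1), n)
            resid = ResidualVariances.from_region(region)
            sigma2 = config_residual_variance([0], region, resid)
            values.append(log_bf([0], region, resid, 0.0025, sigma2))
        assert np.all(np.diff(values) > 0)

    def test_small_effect_limit_matches_unit_residual_model(self):
        """With tiny z the configuration BF agrees with the earlier
        derivation that fixes all residual variances at 1 (D = I)."""
        n = 50_000
        z = np.array([1.2, -0.8, 0.5])
        region = region_from_z(z, np.eye(3) + 0.0, n)
        resid = ResidualVariances.from_region(region)
        d_eye = ResidualVariances(per_variant=np.ones(3), d_half=np.ones(3))
        for config in [(0,), (0, 1), (0, 1, 2)]:
            new = log_bf(config, region, resid, 0.0025, 1.0)
            v11 = log_bf(config, region, d_eye, 0.0025, 1.0)
            assert new == pytest.approx(v11, rel=1e-3, abs=1e-3)


class TestPriorGrid:
    def test_four_point_grid_from_anchor_heritability(self):
        # single variant explaining h2 = 0.16: s_up = sqrt(0.16)/2 = 0.2
        n = 10_000
        z = math.sqrt(n * 0.16 / 0.84)
        region = region_from_z([z], np.eye(1), n)
        resid = ResidualVariances.from_region(region)
        grid = build_prior_grid(region, resid, PriorSettings())
        np.testing.assert_allclose(grid, [0.0025, 0.0150, 0.0275, 0.0400],
                                   atol=1e-12)

    def test_degenerate_grid_collapses_to_baseline(self):
        n = 10_000
        z = math.sqrt(n * 0.0025 / 0.9975)
        region = region_from_z([z], np.eye(1), n)
        resid = ResidualVariances.from_region(region)
        grid = build_prior_grid(region, resid, PriorSettings())
        np.testing.assert_allclose(grid, [0.0025])

    def test_anchor_greedy_skips_highly_correlated(self):
        n = 10_000
        r = np.array([[1.0, 0.99, 0.3], [0.99, 1.0, 0.3], [0.3, 0.3, 1.0]])
        region = region_from_z([15.0, 14.0, 12.0], r, n)
        resid = ResidualVariances.from_region(region)
        anchor = _anchor_configuration(region, resid, 0.01)
        assert anchor == [0, 2]  # variant 1 skipped: |r|=0.99 with variant 0


class TestAveragedLogBF:
    def test_single_point_grid_is_identity(self, identity_region):
        resid = ResidualVariances.from_region(identity_region)
        single = log_bf([1], identity_region, resid, 0.0025,
                        config_residual_variance([1], identity_region, resid))
        avg = averaged_log_bf([1], identity_region, resid, [0.0025])
        assert avg == pytest.approx(single, rel=1e-12)

    def test_two_equal_grid_points(self, identity_region):
        resid = ResidualVariances.from_region(identity_region)
        one = averaged_log_bf([1], identity_region, resid, [0.01])
        two = averaged_log_bf([1], identity_region, resid, [0.01, 0.01])
        assert two == pytest.approx(one, rel=1e-12)

    def test_four_point_grid_against_high_precision_log_mean_exp(self):
        region = region_from_z([6.0, -3.0], np.array([[1.0, 0.4], [0.4, 1.0]]),
                               20_000)
        resid = ResidualVariances.from_region(region)
        grid = [0.0025, 0.01, 0.02, 0.04]
        sigma2 = config_residual_variance([0, 1], region, resid)
        logs = [log_bf([0, 1], region, resid, s2, sigma2) for s2 in grid]
        got = averaged_log_bf([0, 1], region, resid, grid, sigma2_gamma=sigma2)
        assert min(logs) <= got <= max(logs)
        getcontext().prec = 200
        mean = sum(Decimal(v).exp() for v in logs) / Decimal(4)
        assert got == pytest.approx(float(mean.ln()), rel=1e-12)


class TestScoringEngine:
    def test_batch_matches_scalar_path(self, rng):
        _, _, region = individual_dataset(rng, n=500, m=6, betas={2: 0.5})
        resid = ResidualVariances.from_region(region)
        settings = PriorSettings(max_causal=3)
        grid = build_prior_grid(region, resid, settings)
        sets = [(2,), (0, 2), (1, 2, 4), (3,)]
        log_post, avg, _, sigma2, valid = score_configurations(
            sets, region, resid, grid, settings, large_effects=True)
        assert valid.all()
        for i, s in enumerate(sets):
            s2g = config_residual_variance(s, region, resid)
            assert sigma2[i] == pytest.approx(s2g, rel=1e-10)
            expect = averaged_log_bf(s, region, resid, grid, sigma2_gamma=s2g)
            assert avg[i] == pytest.approx(expect, rel=1e-10)
            prior = config_log_prior(len(s), region.m, settings)
            assert log_post[i] == pytest.approx(expect + prior, rel=1e-10)

    def test_ill_conditioned_gets_minus_inf(self):
        r = np.array([[1.0, 1.0 - 1e-12], [1.0 - 1e-12, 1.0]])
        region = region_from_z([5.0, 5.0], r, 1000)
        resid = ResidualVariances.from_region(region)
        settings = PriorSettings(max_causal=2)
        log_post, *_ , valid = score_configurations(
            [(0, 1)], region, resid, np.array([0.0025]), settings, True)
        assert not valid[0] and log_post[0] == -np.inf

    def test_config_prior_normalizes_over_dimensions(self):
        settings = PriorSettings(max_causal=3)
        m = 10
        total = 0.0
        for k in range(1, 4):
            total += math.comb(m, k) * math.exp(config_log_prior(k, m, settings))
        assert total == pytest.approx(1.0, rel=1e-12)
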