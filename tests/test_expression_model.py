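import numpy as np
import pytest

from crtscreen import (
    SimConfig,
    distilled_z,
    distilled_z_all_cells,
    distilled_z_resamples,
    estimate_dispersions,
    fit_reduced_nb,
    full_nb_z,
    gen_covariates,
    gen_zinb_expression,
    moment_dispersion,
    parametric_pvalue,
)


class TestMomentDispersion:
    def test_closed_form(self):
        # e.g. mean 4, sample variance 20 -> alpha = (20-4)/16 = 1
        for m, s2, expected in [(4.0, 20.0, 1.0), (2.0, 10.0, 2.0)]:
            y = _vector_with_moments(m, s2)
            assert moment_dispersion(y) == pytest.approx(expected, rel=1e-12)

    def test_equidispersed_hits_floor(self):
        y = np.array([3.0, 3.0, 3.0, 3.0])  # variance 0 <= mean
        assert moment_dispersion(y) == 0.01

    def test_unexpressed_gene_errors(self):
        with pytest.raises(ValueError, match="unexpressed"):
            moment_dispersion(np.zeros(10))

    def test_variance_identity_on_simulated_nb(self):
        """Var = mu + alpha*mu^2: the estimator recovers alpha from NB draws."""
        rng = np.random.default_rng(0)
        mu, alpha, n = 5.0, 0.8, 200_000
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, n))
        assert moment_dispersion(y) == pytest.approx(alpha, rel=0.05)


def _vector_with_moments(m, s2):
    """Two-point vector with exact sample mean m and sample variance s2."""
    d = np.sqrt(s2 / 2)
    return np.array([m - d, m + d])


class TestDispersionTrend:
    def test_constant_raw_gives_constant_final(self):
        means = np.array([1.0, 2.0, 5.0, 10.0])
        raw = np.full(4, 0.7)
        fit = estimate_dispersions(means, raw)
        np.testing.assert_allclose(fit.final_dispersion, 0.7, rtol=1e-10)

    def test_single_gene_degenerates_to_raw(self):
        fit = estimate_dispersions(np.array([3.0]), np.array([0.5]))
        assert fit.final_dispersion[0] == pytest.approx(0.5)

    def test_projection_recovers_flat_truth(self):
        """200 genes simulated at alpha=0.5: >=90% of final dispersions within 20%."""
        rng = np.random.default_rng(1)
        n_genes, n_cells, alpha = 200, 400, 0.5
        mus = rng.uniform(1.0, 20.0, n_genes)
        raws = []
        for mu in mus:
            y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, n_cells))
            raws.append(moment_dispersion(y))
        fit = estimate_dispersions(mus, np.array(raws))
        frac_close = np.mean(np.abs(fit.final_dispersion - alpha) / alpha < 0.2)
        assert frac_close >= 0.9


class TestReducedNB:
    def test_intercept_only_mle_is_log_mean(self):
        y = np.array([2, 6, 3, 5] * 25)  # mean 4
        fit = fit_reduced_nb(y, np.empty((100, 0)), alpha=1.0)
        assert fit.intercept == pytest.approx(np.log(4), abs=1e-6)
        np.testing.assert_allclose(fit.offsets, np.log(4), atol=1e-6)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_reduced_nb(np.zeros(50), np.ones((50, 1)), alpha=1.0)

    def test_parameter_recovery(self):
        """Estimates land within 3 SE of the generative coefficients at n=5000."""
        rng = np.random.default_rng(2)
        n = 5000
        Z = np.column_stack([rng.binomial(1, 0.5, n), rng.normal(0, 1, n)])
        beta0, gamma = 1.0, np.array([-0.5, 0.3])
        mu = np.exp(beta0 + Z @ gamma)
        alpha = 0.7
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
        fit = fit_reduced_nb(y, Z, alpha)
        # rough SE scale: sqrt of inverse information ~ n^{-1/2} * O(1)
        assert fit.converged
        assert fit.intercept == pytest.approx(beta0, abs=0.15)
        np.testing.assert_allclose(fit.covariate_coefficients, gamma, atol=0.15)

    def test_batch_reference_level_invariance(self, null_screen):
        """Fitted NB means are unchanged by flipping the batch dummy coding."""
        Z, x, y = null_screen
        fit_a = fit_reduced_nb(y, Z, alpha=1.0)
        Zflip = Z.copy()
        Zflip[:, 0] = 1 - Zflip[:, 0]
        fit_b = fit_reduced_nb(y, Zflip, alpha=1.0)
        np.testing.assert_allclose(fit_a.offsets, fit_b.offsets, atol=1e-6)


class TestDistilledStatistic:
    @pytest.mark.parametrize("seed", range(8))
    def test_distillation_equivalence(self, seed):
        """Treated-cells-only refit equals the all-cells offset fit to 1e-6."""
        cfg = SimConfig()
        rng = np.random.default_rng(seed)
        Z = gen_covariates(800, cfg, rng)
        x = (rng.random(800) < 0.05).astype(int)
        x[:3] = 1
        y = gen_zinb_expression(Z, x, cfg.beta, alpha=1.0, lam=0.0, effect=-0.5, seed=rng)
        fit = fit_reduced_nb(y, Z, alpha=1.0)
        d_treated = distilled_z(y, x, fit.offsets, alpha=1.0)
        d_all = distilled_z_all_cells(y, x, fit.offsets, alpha=1.0)
        assert d_treated.z_value == pytest.approx(d_all.z_value, abs=1e-6)
        assert d_treated.beta_hat == pytest.approx(d_all.beta_hat, abs=1e-6)

    def test_agrees_with_full_regression(self, null_screen):
        """Distilled z is close to the joint-regression Wald z."""
        Z, x, y = null_screen
        fit = fit_reduced_nb(y, Z, alpha=1.0)
        d = distilled_z(y, x, fit.offsets, alpha=1.0)
        z_full = full_nb_z(y, x, Z, alpha=1.0)
        assert abs(d.z_value - z_full) < 0.1

    def test_x_all_zero_errors(self, null_screen):
        Z, _, y = null_screen
        fit = fit_reduced_nb(y, Z, alpha=1.0)
        with pytest.raises(ValueError, match="all zeros"):
            distilled_z(y, np.zeros_like(y), fit.offsets, alpha=1.0)
        with pytest.raises(ValueError, match="all zeros"):
            full_nb_z(y, np.zeros_like(y), Z, alpha=1.0)

    def test_strong_repression_gives_large_negative_z(self):
        cfg = SimConfig()
        rng = np.random.default_rng(3)
        Z = gen_covariates(2000, cfg, rng)
        x = (rng.random(2000) < 0.05).astype(int)
        y = gen_zinb_expression(Z, x, cfg.beta, alpha=1.0, lam=0.0, effect=-2.0, seed=rng)
        z_full = full_nb_z(y, x, Z, alpha=1.0)
        assert z_full < -5

    def test_null_z_centered_at_zero(self):
        """Mean distilled z over independent null draws is within 3 SE of 0."""
        cfg = SimConfig()
        rng = np.random.default_rng(4)
        n_rep = 500
        zs = []
        Z = gen_covariates(500, cfg, rng)
        y = gen_zinb_expression(Z, np.zeros(500), cfg.beta, alpha=1.0, lam=0.0, seed=rng)
        fit = fit_reduced_nb(y, Z, alpha=1.0)
        idx = [rng.choice(500, size=25, replace=False) for _ in range(n_rep)]
        zs = distilled_z_resamples(y, fit.offsets, 1.0, idx)
        zs = zs[np.isfinite(zs)]
        se = zs.std(ddof=1) / np.sqrt(zs.size)
        assert abs(zs.mean()) < 3 * se

    def test_resample_solver_matches_scalar_solver(self, null_screen):
        Z, x, y = null_screen
        fit = fit_reduced_nb(y, Z, alpha=1.0)
        idx = [np.flatnonzero(x)]
        z_vec = distilled_z_resamples(y, fit.offsets, 1.0, idx)
        z_scalar = distilled_z(y, x, fit.offsets, 1.0).z_value
        assert z_vec[0] == pytest.approx(z_scalar, abs=1e-8)

    def test_resample_solver_flags_degenerate(self, null_screen):
        Z, x, y = null_screen
        fit = fit_reduced_nb(y, Z, alpha=1.0)
        zero_cells = np.flatnonzero(y == 0)[:5]
        z = distilled_z_resamples(y, fit.offsets, 1.0, [np.array([], dtype=int), zero_cells])
        assert np.isnan(z).all()


class TestParametricPvalue:
    @pytest.mark.parametrize(
        "z,tail,expected",
        [
            (0.0, "two", 1.0),
            (1.96, "right", 0.0250),
            (-1.6449, "left", 0.0500),
            (-1.96, "two", 0.0500),
        ],
    )
    def test_normal_tails(self, z, tail, expected):
        assert parametric_pvalue(z, tail) == pytest.approx(expected, abs=2e-4)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            parametric_pvalue(np.inf, "two")
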