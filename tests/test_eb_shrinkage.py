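import numpy as np
import pytest

from ebgs.eb_shrinkage import (
    EBConfig,
    EBFit,
    blup_given_variances,
    eb_fit,
    marginal_log_posterior,
    predict,
)
from ebgs.errors import NumericalError, ValidationError
from tests.util import design_from_codes, grid_best_log_posterior


def _instance(seed, n=15, p=3, effects=(1.5, -1.0, 0.8), resid_sd=1.0, beta=0.3):
    rng = np.random.default_rng(seed)
    Z = rng.choice([-1, 1], size=(n, p))
    y = beta + Z @ np.asarray(effects[:p]) + rng.normal(0, resid_sd, n)
    return y, design_from_codes(Z)


class TestBlupGivenVariances:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_covariance_solution(self, seed):
        """Line-level algebra agrees with the explicit n x n solve to 1e-8."""
        y, d = _instance(seed)
        rng = np.random.default_rng(100 + seed)
        s2k = rng.uniform(0.05, 2.0, d.n_terms)
        s2 = float(rng.uniform(0.3, 2.0))
        beta, gamma, se = blup_given_variances(y, d, s2k, s2)
        Z = d.columns
        V = (Z * s2k) @ Z.T + s2 * np.eye(len(y))
        Vi = np.linalg.inv(V)
        ones = np.ones(len(y))
        beta0 = ones @ Vi @ y / (ones @ Vi @ ones)
        gamma0 = s2k * (Z.T @ (Vi @ (y - beta0)))
        se0 = np.sqrt(s2k - s2k**2 * np.einsum("ji,jk,ki->i", Z, Vi, Z))
        assert abs(beta - beta0) < 1e-8
        np.testing.assert_allclose(gamma, gamma0, atol=1e-8)
        np.testing.assert_allclose(se, se0, atol=1e-8)

    def test_zero_variances_give_zero_effects(self):
        y, d = _instance(7)
        beta, gamma, se = blup_given_variances(y, d, np.zeros(d.n_terms), 1.3)
        np.testing.assert_array_equal(gamma, 0.0)
        # V = s2 I, so the GLS intercept is the plain mean
        assert abs(beta - y.mean()) < 1e-12

    def test_equals_ridge_on_orthogonal_design(self):
        """Equal variances s2/lambda reproduce ridge with penalty lambda."""
        # 4x4 Hadamard-type orthogonal +-1 block, replicated
        H = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]])
        Z = np.vstack([H, H, H])[:, 1:]  # drop constant column; 12 x 3, orthogonal
        rng = np.random.default_rng(42)
        y = Z @ np.array([2.0, 0.5, -1.0]) + rng.normal(0, 0.5, 12)
        lam = 3.0
        s2 = 0.8
        beta, gamma, _ = blup_given_variances(y, design_from_codes(Z), np.full(3, s2 / lam), s2)
        e = y - beta
        ridge = np.linalg.solve(Z.T @ Z + lam * np.eye(3), Z.T @ e)
        np.testing.assert_allclose(gamma, ridge, atol=1e-8)

    def test_ols_limit_single_column(self):
        rng = np.random.default_rng(8)
        Z = rng.choice([-1, 1], size=(20, 1))
        y = Z[:, 0] * 1.2 + rng.normal(0, 0.4, 20)
        beta, gamma, _ = blup_given_variances(y, design_from_codes(Z), [1e8], 1.0)
        e = y - beta
        ols = float(Z[:, 0] @ e / (Z[:, 0] @ Z[:, 0]))
        assert abs(gamma[0] - ols) < 1e-4

    def test_zero_residual_variance_rejected(self):
        y, d = _instance(9)
        with pytest.raises(NumericalError):
            blup_given_variances(y, d, np.zeros(d.n_terms), 0.0)


class TestMarginalLogPosterior:
    def test_two_by_two_hand_computation(self):
        """n=2, one column: V and its density written out by hand."""
        Z = np.array([[1], [-1]])
        y = np.array([1.0, 0.5])
        s2k, s2 = 0.5, 1.0
        d = design_from_codes(Z)
        # V = [[1.5, -0.5], [-0.5, 1.5]]; det = 2.0; Vi = [[.75,.25],[.25,.75]]
        Vi = np.array([[0.75, 0.25], [0.25, 0.75]])
        ones = np.ones(2)
        beta = ones @ Vi @ y / (ones @ Vi @ ones)
        e = y - beta
        expected = -0.5 * (2 * np.log(2 * np.pi) + np.log(2.0) + e @ Vi @ e)
        got = marginal_log_posterior(y, d, [s2k], s2)
        assert abs(got - expected) < 1e-12

    def test_zero_variance_reduces_to_iid_likelihood(self):
        y, d = _instance(3)
        s2 = 0.9
        got = marginal_log_posterior(y, d, np.zeros(d.n_terms), s2)
        e = y - y.mean()
        iid = -0.5 * (len(y) * np.log(2 * np.pi * s2) + e @ e / s2)
        assert abs(got - iid) < 1e-10

    def test_flat_hyperprior_adds_nothing(self):
        """(tau, omega) = (-2, 0) leaves the pure Gaussian marginal."""
        y, d = _instance(4)
        s2k = np.array([0.4, 1.1, 0.2])
        flat = marginal_log_posterior(y, d, s2k, 1.0, EBConfig(tau=-2.0, omega=0.0))
        informative = marginal_log_posterior(y, d, s2k, 1.0, EBConfig(tau=0.0, omega=0.5))
        prior = np.sum(-1.0 * np.log(s2k) - 0.5 / (2 * s2k) * 1.0)
        # tau=0, omega=0.5: -(tau+2)/2 log s2k - omega/(2 s2k)
        assert abs(informative - (flat + prior)) < 1e-10

    def test_monotone_decrease_for_huge_residual(self):
        y, d = _instance(5)
        s2k = np.full(d.n_terms, 0.1)
        vals = [
            marginal_log_posterior(y, d, s2k, c * np.var(y))
            for c in (10.0, 100.0, 1000.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_non_psd_rejected(self):
        y, d = _instance(6)
        with pytest.raises((NumericalError, ValidationError)):
            marginal_log_posterior(y, d, np.zeros(d.n_terms), -1.0)


class TestEbFit:
    def test_null_data_gives_zero_estimates(self):
        d = design_from_codes(np.random.default_rng(0).choice([-1, 1], (10, 2)))
        fit = eb_fit(np.zeros(10), d)
        assert fit.beta_hat == 0.0
        np.testing.assert_array_equal(fit.gamma_hat, 0.0)
        assert fit.sigma2_resid > 0
        assert fit.converged

    def test_signal_recovered_noise_shrunken(self):
        """Two orthogonal columns, gamma = (2, 0): the null effect shrinks."""
        rng = np.random.default_rng(12)
        base = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]])
        Z = np.vstack([base, base, base])  # n=12, orthogonal columns
        y = Z @ np.array([2.0, 0.0]) + rng.normal(0, 0.3, 12)
        d = design_from_codes(Z)
        fit = eb_fit(y, d, EBConfig(max_sweeps=5000, rel_tol=1e-12))
        assert abs(fit.gamma_hat[0] - 2.0) < 0.3  # within 15%
        assert abs(fit.gamma_hat[1]) < abs(fit.gamma_hat[0]) / 4
        # converged variances essentially maximise the marginal posterior
        ours = marginal_log_posterior(y, d, fit.sigma2_k, fit.sigma2_resid)
        vy = float(np.var(y))
        var_grid = np.concatenate([[1e-8], np.geomspace(1e-3, 10, 14)]) * vy
        resid_grid = np.geomspace(0.02, 5, 14) * vy
        best = grid_best_log_posterior(y, Z.astype(float), var_grid, resid_grid)
        assert ours >= best - 1e-4

    def test_shrinkage_never_exceeds_ols_on_orthogonal_design(self):
        rng = np.random.default_rng(13)
        base = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]])
        Z = np.vstack([base] * 5)
        y = Z @ np.array([1.0, 0.4]) + rng.normal(0, 0.8, 20)
        fit = eb_fit(y, design_from_codes(Z), EBConfig(max_sweeps=2000))
        e = y - y.mean()  # orthogonal columns with zero column sums: OLS intercept = mean
        ols = Z.T @ e / (Z**2).sum(axis=0)
        assert (np.abs(fit.gamma_hat) <= np.abs(ols) + 1e-6).all()

    def test_one_frozen_sweep_equals_blup(self):
        y, d = _instance(21)
        s2k = np.array([0.3, 0.7, 0.1])
        fit = eb_fit(
            y, d, EBConfig(max_sweeps=1, rel_tol=1e-30),
            init_sigma2_k=s2k, init_sigma2_resid=0.9, freeze_variances=True,
        )
        beta, gamma, se = blup_given_variances(y, d, s2k, 0.9)
        assert fit.beta_hat == beta
        np.testing.assert_array_equal(fit.gamma_hat, gamma)
        np.testing.assert_array_equal(fit.se_gamma, se)

    def test_permutation_equivariance(self):
        y, d = _instance(22, n=20)
        cfg = EBConfig(max_sweeps=20000, rel_tol=1e-13)
        fit = eb_fit(y, d, cfg)
        perm = [2, 0, 1]
        d_perm = d.subset_terms(perm)
        fit_p = eb_fit(y, d_perm, cfg)
        np.testing.assert_allclose(fit_p.gamma_hat, fit.gamma_hat[perm], atol=1e-6)
        np.testing.assert_allclose(fit_p.sigma2_k, fit.sigma2_k[perm], rtol=1e-4, atol=1e-10)

    def test_scale_equivariance(self):
        y, d = _instance(23)
        c = 3.7
        cfg = EBConfig(max_sweeps=500)
        fit1 = eb_fit(y, d, cfg)
        fit2 = eb_fit(c * y, d, cfg)
        np.testing.assert_allclose(fit2.gamma_hat, c * fit1.gamma_hat, rtol=1e-8)
        assert np.isclose(fit2.beta_hat, c * fit1.beta_hat, rtol=1e-8)
        np.testing.assert_allclose(fit2.sigma2_k, c**2 * fit1.sigma2_k, rtol=1e-8)
        assert np.isclose(fit2.sigma2_resid, c**2 * fit1.sigma2_resid, rtol=1e-8)

    def test_fixed_point_variance_identity(self):
        """At convergence sigma_k^2 = effect^2 + se^2 (flat hyperprior)."""
        y, d = _instance(24, n=20)
        fit = eb_fit(y, d, EBConfig(max_sweeps=20000, rel_tol=1e-13))
        np.testing.assert_allclose(
            fit.sigma2_k, fit.gamma_hat**2 + fit.se_gamma**2, rtol=1e-5
        )

    def test_replicated_records_equal_expanded_design(self):
        """Line-level compaction is algebraically invisible."""
        rng = np.random.default_rng(25)
        Zl = rng.choice([-1, 1], size=(8, 3))
        rec = np.repeat(np.arange(8), 3)
        y = Zl[rec] @ np.array([1.0, -0.5, 0.0]) + rng.normal(0, 0.7, 24)
        d_compact = design_from_codes(Zl, rec)
        d_expanded = design_from_codes(Zl[rec])
        cfg = EBConfig(max_sweeps=3000, rel_tol=1e-12)
        f1 = eb_fit(y, d_compact, cfg)
        f2 = eb_fit(y, d_expanded, cfg)
        np.testing.assert_allclose(f1.gamma_hat, f2.gamma_hat, atol=1e-8)
        np.testing.assert_allclose(f1.sigma2_resid, f2.sigma2_resid, rtol=1e-6)

    def test_noise_columns_do_not_inflate_strong_effect(self):
        increases = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            z = rng.choice([-1, 1], size=(30, 1))
            y = z[:, 0] * 1.5 + rng.normal(0, 1.0, 30)
            alone = eb_fit(y, design_from_codes(z), EBConfig(max_sweeps=2000))
            noise = rng.choice([-1, 1], size=(30, 8))
            both = eb_fit(
                y, design_from_codes(np.hstack([z, noise])), EBConfig(max_sweeps=2000)
            )
            increases.append(abs(both.gamma_hat[0]) - abs(alone.gamma_hat[0]))
        assert np.median(increases) < 0.02

    def test_non_finite_y_rejected(self):
        _, d = _instance(1)
        with pytest.raises(ValidationError):
            eb_fit(np.array([1.0, np.nan] + [0.0] * 13), d)

    def test_degenerate_column_pinned(self):
        Z = np.column_stack([np.ones(10, dtype=int), np.resize([1, -1], 10)])
        rng = np.random.default_rng(30)
        y = Z[:, 1] * 1.0 + rng.normal(0, 0.5, 10)
        fit = eb_fit(y, design_from_codes(Z), EBConfig(max_sweeps=500))
        assert fit.degenerate[0] and not fit.degenerate[1]
        assert abs(fit.gamma_hat[0]) < 1e-8


class TestPredict:
    def _fit(self):
        Z = np.array([[1], [-1]])
        d = design_from_codes(Z)
        return (
            EBFit(
                terms=list(d.terms), beta_hat=1.0, gamma_hat=np.array([0.5]),
                se_gamma=np.array([0.1]), sigma2_k=np.array([0.3]),
                sigma2_resid=1.0, sweeps_run=1, converged=True,
                config=EBConfig(), design=d,
            ),
            d,
        )

    def test_hand_example(self):
        fit, d = self._fit()
        np.testing.assert_allclose(predict(fit, d), [1.5, 0.5])

    def test_intercept_only(self):
        fit, d = self._fit()
        np.testing.assert_allclose(predict(fit, d, included_terms=[]), [1.0, 1.0])

    def test_missing_term_rejected(self):
        fit, d = self._fit()
        with pytest.raises(ValidationError, match="M9"):
            predict(fit, d, included_terms=["M9"])

    def test_interpolation_limit_with_huge_variances(self):
        rng = np.random.default_rng(31)
        Z = rng.choice([-1, 1], size=(10, 12))
        y = rng.normal(0, 1, 10)
        d = design_from_codes(Z)
        beta, gamma, se = blup_given_variances(y, d, np.full(12, 1e8), 1.0)
        fit = EBFit(
            terms=list(d.terms), beta_hat=beta, gamma_hat=gamma, se_gamma=se,
            sigma2_k=np.full(12, 1e8), sigma2_resid=1.0, sweeps_run=1,
            converged=True, config=EBConfig(), design=d,
        )
        np.testing.assert_allclose(predict(fit, d), y, atol=1e-3)
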