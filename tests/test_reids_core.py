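"""Unit and distributional tests for the mixed-model Gibbs sampler."""

import numpy as np
import pytest
from scipy import stats

from reids.reids_core import (
    ChainSettings,
    PriorSpec,
    exon_score,
    fit_reids_gene,
    update_fixed_effects,
    update_random_effects,
    update_variances,
)

from conftest import make_tensor


class TestExonScore:
    def test_equity_threshold_when_variances_equal(self):
        assert exon_score(1.0, 1.0) == 0.5
        assert exon_score(0.3, 0.3) == 0.5

    def test_arithmetic_and_boundary(self):
        assert exon_score(4.0, 1.0) == pytest.approx(0.8)
        assert exon_score(0.0, 1.0) == 0.0

    def test_vectorized(self):
        np.testing.assert_allclose(exon_score([1.0, 4.0], 1.0), [0.5, 0.8])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exon_score(-0.1, 1.0)
        with pytest.raises(ValueError):
            exon_score(1.0, 0.0)


def _conjugate_b_posterior(residual_sum, n_k, tau2, sigma2):
    """Independent 1-D conjugate posterior: prior N(0, tau2), n_k
    observations of b with noise variance sigma2."""
    prec = 1.0 / tau2 + n_k / sigma2
    return (residual_sum / sigma2) / prec, 1.0 / prec


class TestRandomEffectsUpdate:
    def _tensor(self):
        # n=2 arrays, K=1 exon, 2 probes; residuals {1, 3} on array 1,
        # {-1, 0} on array 2 (p = c = 0)
        return make_tensor([[1.0, 3.0], [-1.0, 0.0]], n_exons=1)

    def test_matches_one_dimensional_conjugate_posterior(self):
        tensor = self._tensor()
        rng = np.random.default_rng(1)
        p, c = np.zeros(2), np.zeros(2)
        draws = np.array(
            [
                update_random_effects(tensor, p, c, np.array([1.0]), 1.0, rng)[0, 0]
                for _ in range(100_000)
            ]
        )
        mean, var = _conjugate_b_posterior(4.0, 2, 1.0, 1.0)
        assert mean == pytest.approx(4.0 / 3.0)
        ks = stats.kstest(draws, stats.norm(mean, np.sqrt(var)).cdf)
        assert ks.pvalue > 0.01

    def test_large_tau2_limit_is_mean_residual(self, rng):
        tensor = self._tensor()
        draws = update_random_effects(
            tensor, np.zeros(2), np.zeros(2), np.array([1e12]), 1e-8, rng
        )
        np.testing.assert_allclose(draws[:, 0], [2.0, -0.5], atol=1e-3)

    def test_small_tau2_limit_shrinks_to_zero(self, rng):
        tensor = self._tensor()
        draws = update_random_effects(
            tensor, np.zeros(2), np.zeros(2), np.array([1e-12]), 1.0, rng
        )
        np.testing.assert_allclose(draws, 0.0, atol=1e-4)

    def test_nonfinite_inputs_rejected(self, rng):
        tensor = self._tensor()
        with pytest.raises(ValueError):
            update_random_effects(
                tensor, np.array([np.nan, 0.0]), np.zeros(2), np.array([1.0]), 1.0, rng
            )


class TestVarianceUpdate:
    def test_tau2_inverse_gamma_mean(self, rng):
        # all b = 0, psi = K = 1, n = 4, omega = 1 -> IG(2.5, 0.5), mean 1/3
        tensor = make_tensor(np.zeros((4, 2)), n_exons=1)
        prior = PriorSpec(psi=1.0)
        p, c, b = np.zeros(2), np.zeros(4), np.zeros((4, 1))
        draws = np.array(
            [update_variances(tensor, p, c, b, prior, rng)[0][0] for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(1.0 / 3.0, abs=0.01)
        ks = stats.kstest(draws, stats.invgamma(2.5, scale=0.5).cdf)
        assert ks.pvalue > 0.01

    def test_sigma2_conjugate_form_under_perfect_fit(self, rng):
        # zero residuals, N = 100 observations -> 1/sigma2 ~ Gamma(50.0001, rate 1e-4)
        tensor = make_tensor(np.zeros((10, 10)), n_exons=1)
        prior = PriorSpec()
        p, c, b = np.zeros(10), np.zeros(10), np.zeros((10, 1))
        sig = np.array(
            [update_variances(tensor, p, c, b, prior, rng)[1] for _ in range(100_000)]
        )
        expected_mean = 1e-4 / (50.0001 - 1)
        assert sig.mean() == pytest.approx(expected_mean, rel=0.02)
        ks = stats.kstest(1.0 / sig, stats.gamma(50.0001, scale=1.0 / 1e-4).cdf)
        assert ks.pvalue > 0.01

    def test_sigma2_density_matches_independent_form(self, rng):
        # general residuals: 1/sigma2 ~ Gamma(alpha + N/2, rate beta + SSR/2)
        Y = np.array([[1.0, -2.0, 0.5], [0.3, 0.1, -0.7]])
        tensor = make_tensor(Y, n_exons=1)
        prior = PriorSpec(alpha=2.0, beta=1.5)
        p, c, b = np.zeros(3), np.zeros(2), np.zeros((2, 1))
        sig = np.array(
            [update_variances(tensor, p, c, b, prior, rng)[1] for _ in range(100_000)]
        )
        ssr = float((Y**2).sum())
        ks = stats.kstest(
            1.0 / sig, stats.gamma(2.0 + 3.0, scale=1.0 / (1.5 + ssr / 2)).cdf
        )
        assert ks.pvalue > 0.01


class TestFixedEffectsUpdate:
    def test_noiseless_additive_recovery(self, rng):
        p_true = np.array([2.0, 5.0, 3.0, 4.0])
        c_true = np.array([1.0, -0.5, 2.5])
        Y = c_true[:, None] + p_true[None, :]
        tensor = make_tensor(Y, n_exons=2)
        b = np.zeros((3, 2))
        p, c = update_fixed_effects(tensor, b, 1e-12, rng)
        np.testing.assert_allclose(c, c_true - c_true.mean(), atol=1e-5)
        np.testing.assert_allclose(p, p_true + c_true.mean(), atol=1e-5)

    def test_single_array_centres_to_zero(self, rng):
        Y = np.array([[3.0, 7.0]])
        tensor = make_tensor(Y, n_exons=1)
        p, c = update_fixed_effects(tensor, np.zeros((1, 1)), 1e-12, rng)
        assert c[0] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(p, [3.0, 7.0], atol=1e-5)

    def test_stationary_mean_matches_least_squares_oracle(self, rng):
        # Gibbs sub-chain on (p, c) given b, sigma2 has the constrained
        # least-squares solution as its stationary mean.
        n, J = 3, 4
        Y = rng.normal(size=(n, J)) + rng.normal(size=(1, J)) * 2
        tensor = make_tensor(Y, n_exons=2)
        b = rng.normal(size=(n, 2)) * 0.5
        sigma2 = 0.1

        # independent oracle: explicit design matrix least squares
        R = Y - b[:, tensor.exon_of_probe]
        X = np.zeros((n * J, J + n))
        for i in range(n):
            for j in range(J):
                X[i * J + j, j] = 1.0
                X[i * J + j, J + i] = 1.0
        beta, *_ = np.linalg.lstsq(X, R.ravel(), rcond=None)
        p_ls, c_ls = beta[:J], beta[J:]
        shift = c_ls.mean()
        p_ls, c_ls = p_ls + shift, c_ls - shift

        p, c = np.zeros(J), np.zeros(n)
        p_sum, c_sum = np.zeros(J), np.zeros(n)
        n_sweeps = 4000
        for s in range(n_sweeps):
            p, c = update_fixed_effects(tensor, b, sigma2, rng, c_current=c)
            if s >= 1000:
                p_sum += p
                c_sum += c
        np.testing.assert_allclose(p_sum / 3000, p_ls, atol=0.05)
        np.testing.assert_allclose(c_sum / 3000, c_ls, atol=0.05)


class TestFullFit:
    def _spliced_tensor(self, rng, n=12, K=4, m=3, delta=4.0):
        p = rng.normal(7, 1, size=K * m)
        c = rng.normal(0, 1, size=n)
        Y = p[None, :] + c[:, None] + rng.normal(0, 0.5, size=(n, K * m))
        spliced = rng.random(n) < 0.5
        Y[np.ix_(spliced, np.arange(m))] -= delta  # exon 0 depleted
        return make_tensor(Y, n_exons=K)

    def test_location_invariance_of_scores(self, rng):
        tensor = self._spliced_tensor(rng)
        chain = ChainSettings(n_iter=400, n_burnin=200, seed=42)
        fit1 = fit_reids_gene(tensor, chain=chain)
        shifted = make_tensor(tensor.Y + 5.0, n_exons=tensor.n_exons)
        fit2 = fit_reids_gene(shifted, chain=chain)
        np.testing.assert_allclose(fit2.p, fit1.p + 5.0, atol=1e-8)
        np.testing.assert_allclose(fit2.exon_scores, fit1.exon_scores, atol=1e-10)
        np.testing.assert_allclose(fit2.array_scores, fit1.array_scores, atol=1e-8)

    def test_array_permutation_equivariance(self, rng):
        tensor = self._spliced_tensor(rng, n=16)
        chain = ChainSettings(n_iter=5000, n_burnin=1000, seed=3)
        fit = fit_reids_gene(tensor, chain=chain)
        perm = rng.permutation(tensor.n_arrays)
        permuted = make_tensor(tensor.Y[perm], n_exons=tensor.n_exons)
        fit_p = fit_reids_gene(permuted, chain=chain.with_seed(4))
        np.testing.assert_allclose(fit_p.exon_scores, fit.exon_scores, atol=0.1)
        np.testing.assert_allclose(fit_p.c, fit.c[perm], atol=0.15)
        np.testing.assert_allclose(fit_p.array_scores, fit.array_scores[perm], atol=0.25)

    def test_spliced_exon_attains_highest_score(self, rng):
        hits = 0
        for rep in range(10):
            tensor = self._spliced_tensor(rng, n=20)
            fit = fit_reids_gene(
                tensor, chain=ChainSettings(n_iter=600, n_burnin=300, seed=rep)
            )
            if fit.exon_scores[0] == fit.exon_scores.max() and fit.exon_scores[0] > 0.5:
                hits += 1
        assert hits >= 9

    def test_null_data_scores_below_equity(self, rng):
        # pure probe effects + noise: no between-array structure
        scores = []
        for rep in range(8):
            p = rng.normal(7, 1, size=12)
            Y = p[None, :] + rng.normal(0, 0.5, size=(20, 12))
            fit = fit_reids_gene(
                make_tensor(Y, n_exons=4),
                chain=ChainSettings(n_iter=600, n_burnin=300, seed=rep),
            )
            scores.extend(fit.exon_scores)
        assert np.median(scores) < 0.5

    def test_constant_data_completes_without_failure(self):
        # degenerate: no noise, no splicing.  sigma2 collapses toward its
        # vague prior (near 0) while tau2 stays at its prior scale, so the
        # scores are prior-driven; the contract is numerical stability.
        tensor = make_tensor(np.full((6, 8), 9.5), n_exons=2)
        fit = fit_reids_gene(tensor, chain=ChainSettings(n_iter=400, n_burnin=200, seed=0))
        assert np.all(np.isfinite(fit.exon_scores))
        assert np.all(np.abs(fit.array_scores) < 0.05)
        assert fit.sigma2 < 1e-3

    def test_reproducible_given_seed(self, rng):
        tensor = self._spliced_tensor(rng)
        chain = ChainSettings(n_iter=300, n_burnin=100, seed=11)
        f1 = fit_reids_gene(tensor, chain=chain)
        f2 = fit_reids_gene(tensor, chain=chain)
        np.testing.assert_array_equal(f1.exon_scores, f2.exon_scores)
        np.testing.assert_array_equal(f1.array_scores, f2.array_scores)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2 arrays"):
            fit_reids_gene(make_tensor([[1.0, 2.0]], n_exons=1))
        with pytest.raises(ValueError):
            ChainSettings(n_iter=10, n_burnin=10)
        with pytest.raises(ValueError):
            ChainSettings(n_iter=10, n_burnin=5, thin=0)
        with pytest.raises(ValueError):
            PriorSpec(alpha=0.0)


class TestStationaryDistribution:
    def test_gibbs_matches_grid_posterior_on_minimal_gene(self):
        """With p = c = 0 held fixed, the (b, tau2, sigma2) Gibbs chain on a
        one-probe, one-exon, two-array gene must converge to the posterior
        p(tau2, sigma2 | y) obtained by integrating b out analytically
        (y_i ~ N(0, tau2 + sigma2)) and evaluating priors on a dense grid."""
        y = np.array([[1.0], [-0.5]])
        tensor = make_tensor(y, n_exons=1)
        prior = PriorSpec(alpha=3.0, beta=2.0, psi=3.0, omega_diag=2.0)
        rng = np.random.default_rng(202)

        p0, c0 = np.zeros(1), np.zeros(2)
        tau2, sigma2 = np.array([1.0]), 1.0
        tau2_draws = []
        n_iter, burn, thin = 120_000, 2000, 20
        for it in range(n_iter):
            b = update_random_effects(tensor, p0, c0, tau2, sigma2, rng)
            tau2, sigma2 = update_variances(tensor, p0, c0, b, prior, rng)
            if it >= burn and it % thin == 0:
                tau2_draws.append(tau2[0])
        tau2_draws = np.array(tau2_draws)

        # independent grid oracle
        tg = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 600))
        sg = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 600))
        T, S = np.meshgrid(tg, sg, indexing="ij")
        log_prior = stats.invgamma(prior.psi_for(1) / 2, scale=prior.omega_diag / 2
                                   ).logpdf(T) + stats.invgamma(
            prior.alpha, scale=prior.beta
        ).logpdf(S)
        V = T + S
        loglik = -0.5 * ((y**2).sum() / V) - len(y) / 2 * np.log(2 * np.pi * V)
        # log-grid integration weights d(tau2) d(sigma2) = T S dlog T dlog S
        logw = log_prior + loglik + np.log(T) + np.log(S)
        w = np.exp(logw - logw.max())
        marg_tau = w.sum(axis=1)
        cdf_tau = np.cumsum(marg_tau) / marg_tau.sum()

        emp_cdf = np.searchsorted(np.sort(tau2_draws), tg, side="right") / len(
            tau2_draws
        )
        assert np.max(np.abs(emp_cdf - cdf_tau)) < 0.04
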