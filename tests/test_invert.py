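"""Variational Laplace: priors, free energy, conjugate exactness, recovery."""

import numpy as np
import pytest
from scipy import stats

from speechdcm import (
    CohortSpec, ConnectivityParams, DCMParameters, FitOptions, GaussianBelief,
    NoisePrior, build_effective_A, default_priors, fit_gaussian_nonlinear,
    fit_vl, free_energy, predict_bold, simulate_cohort,
)
from speechdcm.invert import NoiseModel, _kl_gaussian


def linear_forward(X):
    """A linear surrogate forward model y = X theta, batched."""
    def forward_batch(thetas):
        thetas = np.atleast_2d(thetas)
        Y = thetas @ X.T
        return Y[:, :, None], np.ones(thetas.shape[0], bool)
    return forward_batch


def conjugate_posterior(X, y, prior, sigma2):
    """Closed-form Gaussian posterior and log evidence for y = X theta + e."""
    P0 = np.linalg.inv(prior.cov)
    H = X.T @ X / sigma2 + P0
    cov = np.linalg.inv(H)
    mean = cov @ (X.T @ y / sigma2 + P0 @ prior.mean)
    evidence = stats.multivariate_normal.logpdf(
        y, X @ prior.mean, sigma2 * np.eye(y.size) + X @ prior.cov @ X.T)
    return GaussianBelief(mean, 0.5 * (cov + cov.T)), float(evidence)


class TestDefaultPriors:
    def test_prior_mean_self_connection(self, spec, priors):
        prior, _ = priors
        theta = DCMParameters.from_vector(prior.mean, spec)
        A = build_effective_A(theta.conn, spec)
        assert np.allclose(np.diag(A), -0.5)

    def test_extrinsic_mass_within_plotting_range(self, spec, priors):
        prior, _ = priors
        sd = np.sqrt(np.diag(prior.cov)[:len(spec.extrinsic_pairs())])
        assert (sd == 0.5).all()
        mass = stats.norm.cdf(1, 0, 0.5) - stats.norm.cdf(-1, 0, 0.5)
        assert mass > 0.95

    def test_prior_mean_prediction_is_finite(self, spec, word_design, priors):
        prior, _ = priors
        theta = DCMParameters.from_vector(prior.mean, spec)
        ts = predict_bold(theta, word_design, spec)
        assert np.isfinite(ts.values).all()


class TestFreeEnergy:
    def test_kl_vanishes_at_the_prior(self, priors):
        prior, _ = priors
        assert _kl_gaussian(prior, prior) == pytest.approx(0.0, abs=1e-10)

    def test_linear_model_free_energy_equals_log_evidence(self):
        rng = np.random.default_rng(0)
        n, p = 40, 3
        X = rng.normal(size=(n, p))
        prior = GaussianBelief(np.zeros(p), np.diag([1.0, 0.5, 2.0]))
        sigma2 = 0.3
        theta_true = np.array([0.5, -1.0, 0.2])
        y = X @ theta_true + rng.normal(0, np.sqrt(sigma2), n)
        post, evidence = conjugate_posterior(X, y, prior, sigma2)
        lam = np.array([-np.log(sigma2)])
        est = fit_gaussian_nonlinear(
            linear_forward(X), y[:, None], prior,
            NoisePrior(mean=lam, variance=1.0),
            FitOptions(update_noise=False, tol=1e-12, patience=6,
                       max_iter=200))
        assert est.free_energy == pytest.approx(evidence, rel=1e-6)

    def test_shrinking_residuals_increases_f(self, spec, word_design, priors):
        prior, noise_prior = priors
        theta = DCMParameters(ConnectivityParams.from_dict(
            spec, extrinsic={("A1", "pSTS"): 0.4}, input_gain=0.15))
        clean = predict_bold(theta, word_design, spec)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.1, clean.values.shape)
        belief = GaussianBelief(theta.flatten(spec), prior.cov)
        nm = NoiseModel(np.zeros(4))
        f_small = free_energy(belief, nm, clean, prior, word_design, spec,
                              noise_prior=noise_prior)
        noisy = type(clean)(clean.values + noise, clean.tr,
                            clean.region_labels)
        f_large = free_energy(belief, nm, noisy, prior, word_design, spec,
                              noise_prior=noise_prior)
        assert f_small > f_large


class TestFitVL:
    def test_zero_iterations_returns_the_prior(self, spec, word_design,
                                               priors, fitted_subject):
        prior, _ = priors
        record, _ = fitted_subject
        cohort = CohortSpec(n_subjects=1, tasks=("word",),
                            configurations=("M1-f&dpOp",), seed=7)
        series, _ = simulate_cohort(cohort)
        est = fit_vl(series[(0, "word", "M1-f&dpOp")], word_design, spec,
                     opts=FitOptions(max_iter=0))
        assert np.array_equal(est.belief.mean, prior.mean)
        assert np.array_equal(est.belief.cov, prior.cov)

    def test_linear_model_matches_conjugate_solution(self):
        rng = np.random.default_rng(3)
        n, p = 60, 4
        X = rng.normal(size=(n, p))
        prior = GaussianBelief(np.full(p, 0.1), np.eye(p) * 0.8)
        sigma2 = 0.5
        y = X @ rng.normal(size=p) + rng.normal(0, np.sqrt(sigma2), n)
        post, _ = conjugate_posterior(X, y, prior, sigma2)
        est = fit_gaussian_nonlinear(
            linear_forward(X), y[:, None], prior,
            NoisePrior(mean=np.array([-np.log(sigma2)]), variance=1.0),
            FitOptions(update_noise=False, tol=1e-12, patience=6,
                       max_iter=200))
        assert np.abs(est.belief.mean - post.mean).max() \
            <= 1e-6 * np.abs(post.mean).max()
        assert np.abs(est.belief.cov - post.cov).max() \
            <= 1e-6 * np.abs(post.cov).max()

    def test_free_energy_trace_monotone(self, fitted_subject):
        _, est = fitted_subject
        diffs = np.diff(est.f_trace)
        assert (diffs >= -1e-9).all()
        assert est.converged

    def test_posterior_covariance_positive_definite(self, fitted_subject):
        _, est = fitted_subject
        np.linalg.cholesky(est.belief.cov)  # raises if not PD

    def test_recovers_strongest_planted_connections(self, spec,
                                                    fitted_subject):
        record, est = fitted_subject
        truth = record.theta.flatten(spec)
        n_ext = len(spec.extrinsic_pairs())
        order = np.argsort(-np.abs(truth[:n_ext]))[:2]
        for i in order:
            assert np.sign(est.belief.mean[i]) == np.sign(truth[i])
            assert abs(est.belief.mean[i] - truth[i]) < 0.5 * abs(truth[i])

    def test_bit_reproducible(self, spec, word_design):
        cohort = CohortSpec(n_subjects=1, tasks=("word",),
                            configurations=("M1-f&dpOp",), seed=11)
        series, _ = simulate_cohort(cohort)
        ts = series[(0, "word", "M1-f&dpOp")]
        opts = FitOptions(max_iter=6)
        with pytest.warns(RuntimeWarning):
            a = fit_vl(ts, word_design, spec, opts=opts)
        with pytest.warns(RuntimeWarning):
            b = fit_vl(ts, word_design, spec, opts=opts)
        assert np.array_equal(a.belief.mean, b.belief.mean)
        assert np.array_equal(a.belief.cov, b.belief.cov)
        assert a.free_energy == b.free_energy

    def test_recovery_improves_with_less_noise(self, spec, word_design):
        """Rank correlation between true and estimated extrinsic rates
        rises as measurement noise shrinks."""
        cohort = CohortSpec(n_subjects=1, tasks=("word",),
                            configurations=("M1-f&dpOp",), seed=5,
                            noise_sd=0.0)
        series, records = simulate_cohort(cohort)
        clean = series[(0, "word", "M1-f&dpOp")]
        truth = records[0].theta.flatten(spec)
        n_ext = len(spec.extrinsic_pairs())
        rng = np.random.default_rng(17)
        noise_unit = rng.normal(size=clean.values.shape)
        rhos = []
        for frac in (0.6, 0.05):
            noisy = type(clean)(
                clean.values + frac * clean.values.std(axis=0) * noise_unit,
                clean.tr, clean.region_labels)
            est = fit_vl(noisy, word_design, spec)
            rho = stats.spearmanr(truth[:n_ext],
                                  est.belief.mean[:n_ext]).statistic
            rhos.append(rho)
        assert rhos[1] > rhos[0] or rhos[1] > 0.95
        assert rhos[1] > 0.8
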