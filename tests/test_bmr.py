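"""Bayesian model reduction: exactness on conjugate models, model-space
bookkeeping, and connection posterior probabilities."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from speechdcm import (
    GaussianBelief, bayesian_model_reduce, default_network, default_priors,
    enumerate_model_space, score_model_space,
)
from speechdcm.bmr import SHRINK_VARIANCE, reduced_prior_for_mask


def exact_linear_fit(X, y, prior_cov, sigma2):
    """Conjugate posterior + log evidence for y = X theta + e (oracle)."""
    P0 = np.linalg.inv(prior_cov)
    H = X.T @ X / sigma2 + P0
    cov = np.linalg.inv(H)
    mean = cov @ (X.T @ y / sigma2)
    ev = stats.multivariate_normal.logpdf(
        y, np.zeros(y.size), sigma2 * np.eye(y.size) + X @ prior_cov @ X.T)
    return GaussianBelief(mean, 0.5 * (cov + cov.T)), float(ev)


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(8)
    n, p = 50, 2
    X = rng.normal(size=(n, p))
    sigma2 = 0.4
    y = X @ np.array([0.8, 0.0]) + rng.normal(0, np.sqrt(sigma2), n)
    return X, y, sigma2


class TestBayesianModelReduce:
    def test_identity_reduction(self):
        rng = np.random.default_rng(2)
        p = 5
        Q = rng.normal(size=(p, p))
        prior = GaussianBelief(np.zeros(p), np.eye(p))
        post = GaussianBelief(rng.normal(size=p),
                              0.1 * (Q @ Q.T + p * np.eye(p)))
        reduced, df = bayesian_model_reduce(prior, post, prior)
        assert df == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(reduced.mean, post.mean, atol=1e-10)
        assert np.allclose(reduced.cov, post.cov, atol=1e-10)

    def test_matches_exact_evidence_difference(self, linear_problem):
        """dF from the reduction formula equals the difference of exact
        log evidences of the full and reduced conjugate models."""
        X, y, sigma2 = linear_problem
        full_cov = np.diag([1.0, 1.0])
        red_cov = np.diag([1.0, SHRINK_VARIANCE])
        full_post, ev_full = exact_linear_fit(X, y, full_cov, sigma2)
        red_post, ev_red = exact_linear_fit(X, y, red_cov, sigma2)
        prior = GaussianBelief(np.zeros(2), full_cov)
        reduced_prior = GaussianBelief(np.zeros(2), red_cov)
        got_post, got_df = bayesian_model_reduce(prior, full_post,
                                                 reduced_prior)
        assert got_df == pytest.approx(ev_red - ev_full, abs=1e-8)
        assert np.allclose(got_post.mean, red_post.mean, atol=1e-8)

    def test_pruning_a_strong_effect_loses_evidence(self):
        prior = GaussianBelief(np.zeros(1), np.eye(1))
        post = GaussianBelief(np.array([0.5]), np.array([[0.01]]))  # 5 sd
        reduced_prior = GaussianBelief(np.zeros(1),
                                       np.array([[SHRINK_VARIANCE]]))
        _, df = bayesian_model_reduce(prior, post, reduced_prior)
        assert df < 0

    def test_transitive(self):
        rng = np.random.default_rng(4)
        p = 4
        prior_a = GaussianBelief(np.zeros(p), np.eye(p))
        Q = rng.normal(size=(p, p))
        post = GaussianBelief(rng.normal(size=p),
                              0.05 * (Q @ Q.T + p * np.eye(p)))
        prior_b = GaussianBelief(np.zeros(p), np.diag([1, 1, 0.1, 1.0]))
        prior_c = GaussianBelief(np.zeros(p), np.diag([1, 1, 0.1, 1e-4]))
        post_ac, df_ac = bayesian_model_reduce(prior_a, post, prior_c)
        post_ab, df_ab = bayesian_model_reduce(prior_a, post, prior_b)
        post_bc, df_bc = bayesian_model_reduce(prior_b, post_ab, prior_c)
        assert df_ac == pytest.approx(df_ab + df_bc, abs=1e-8)
        assert np.allclose(post_ac.mean, post_bc.mean, atol=1e-8)


class TestModelSpace:
    def test_default_space_has_256_models(self, spec, priors):
        prior, _ = priors
        space = enumerate_model_space(spec, prior)
        assert len(space) == 256

    def test_masks_unique_and_full_model_included(self, spec, priors):
        prior, _ = priors
        space = enumerate_model_space(spec, prior)
        masks = {tuple(m.mask.tolist()) for m in space}
        assert len(masks) == len(space)
        assert tuple([True] * 8) in masks

    def test_empty_switchable_set_gives_single_model(self, priors):
        prior, _ = priors
        spec = default_network()
        frozen = dataclasses.replace(
            spec, switchable_mask=np.zeros((4, 4), bool))
        space = enumerate_model_space(frozen, prior)
        assert len(space) == 1

    def test_combinatorial_guard(self, priors):
        prior, _ = priors
        spec = default_network()
        wide = dataclasses.replace(
            spec,
            switchable_mask=spec.connection_mask & ~np.eye(4, dtype=bool))
        # 11 switchable is allowed; fake more by raising the mask count
        import speechdcm.bmr as bmr
        old = bmr.MAX_SWITCHABLE
        bmr.MAX_SWITCHABLE = 10
        try:
            with pytest.raises(ValueError, match="refusing"):
                enumerate_model_space(wide, prior)
        finally:
            bmr.MAX_SWITCHABLE = old


class TestScoreModelSpace:
    def test_probabilities_match_brute_force_softmax(self, fitted_subject,
                                                     spec, priors):
        """On an 8-model space (3 switchable connections) the model
        probabilities equal directly normalised exp(dF)."""
        prior, _ = priors
        sw = np.zeros((4, 4), bool)
        for s, t in [(1, 3), (2, 3), (1, 2)]:
            sw[s, t] = True
        small = dataclasses.replace(spec, switchable_mask=sw)
        _, est = fitted_subject
        space = enumerate_model_space(small, prior)
        res = score_model_space(est, prior, space, small)
        assert len(space) == 8
        brute = np.array([bayesian_model_reduce(
            prior, est.belief, m.reduced_prior)[1] for m in space])
        expected = np.exp(brute - brute.max())
        expected /= expected.sum()
        assert np.allclose(res.probabilities, expected, atol=1e-12)
        # presence probability = summed probability of models with the
        # connection, recounted by brute force
        for j in range(3):
            assert res.pp[j] == pytest.approx(
                expected[[m.mask[j] for m in space]].sum(), abs=1e-12)

    def test_probabilities_normalised_and_pp_bounded(self, fitted_subject,
                                                     spec, priors):
        prior, _ = priors
        _, est = fitted_subject
        space = enumerate_model_space(spec, prior)
        res = score_model_space(est, prior, space, spec)
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
        assert ((res.pp >= 0) & (res.pp <= 1)).all()

    def test_full_model_only_space_has_certain_connections(self, spec,
                                                           priors,
                                                           fitted_subject):
        prior, _ = priors
        _, est = fitted_subject
        full = [m for m in enumerate_model_space(spec, prior)
                if m.mask.all()]
        res = score_model_space(est, prior, full, spec)
        assert np.allclose(res.pp, 1.0)

    def test_planted_connection_detected(self, fitted_subject, spec, priors):
        """The generated subject carries a strong pSTS -> M1 rate; model
        averaging should report it present with high probability."""
        prior, _ = priors
        record, est = fitted_subject
        truth = record.theta.conn.extrinsic[spec.pair_index("pSTS", "M1")]
        assert truth > 0.3  # planted by the archetype
        space = enumerate_model_space(spec, prior)
        res = score_model_space(est, prior, space, spec)
        assert res.connection_pp(spec, "pSTS", "M1") > 0.75
        assert res.connection_mean(spec, "pSTS", "M1") > 0
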