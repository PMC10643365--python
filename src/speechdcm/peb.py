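"""Parametric empirical Bayes over subject-level posteriors.

Second-level model: theta_i = (x_i' (x) I) beta + eps_i with
eps_i ~ N(0, Sigma_b), where x_i is subject i's row of the design matrix
(default: a single column of ones, i.e. a group mean) and Sigma_b is a
between-subject covariance, modelled as a single log-scaled diagonal
Sigma_b = exp(gamma_b) * (first-level prior covariance / 16).

Because the first level was fitted by variational Laplace, each subject
contributes a Gaussian likelihood over beta obtained by re-weighting its
posterior from the original prior to the empirical prior
N((x_i' (x) I) beta, Sigma_b) -- the same algebra as Bayesian model
reduction.  For fixed gamma_b the beta posterior and the total second-level
free energy are therefore closed-form; gamma_b is optimised on a coarse
grid followed by local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .invert import GaussianBelief, PosteriorEstimate
from .bmr import (ModelSpaceResult, enumerate_model_space, score_model_space)
from .model import NetworkSpec

__all__ = ["PEBModel", "GroupPosterior", "fit_peb", "peb_model_search"]


@dataclass
class PEBModel:
    """Second-level design and hyperparameter settings."""

    design_matrix: np.ndarray            # (n_subjects, n_covariates)
    beta_prior: GaussianBelief           # over one covariate's effects
    base_between_cov: np.ndarray         # Sigma_b at gamma_b = 0 (diagonal)
    gamma_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-4.0, 4.0, 17))
    n_refinements: int = 3

    def __post_init__(self):
        self.design_matrix = np.atleast_2d(np.asarray(self.design_matrix, float))
        if np.linalg.matrix_rank(self.design_matrix) < self.design_matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.base_between_cov = np.asarray(self.base_between_cov, float)
        np.linalg.cholesky(self.base_between_cov)

    @classmethod
    def group_mean(cls, n_subjects: int, subject_prior: GaussianBelief,
                   **kwargs) -> "PEBModel":
        """Default model: one group-mean effect per parameter, with the
        between-subject base covariance = subject prior covariance / 16 and
        second-level priors inherited from the first level."""
        return cls(
            design_matrix=np.ones((n_subjects, 1)),
            beta_prior=GaussianBelief(subject_prior.mean.copy(),
                                      subject_prior.cov.copy()),
            base_between_cov=np.diag(np.diag(subject_prior.cov)) / 16.0,
            **kwargs,
        )


@dataclass
class GroupPosterior:
    beta_belief: GaussianBelief          # stacked (n_covariates * p)
    gamma_b: float
    second_level_f: float
    n_subjects: int
    n_covariates: int


def _subject_terms(posteriors, subject_prior, Pi_b):
    """Per-subject quadratic contribution to the beta likelihood.

    ln p(y_i | m_i) = const_i - 1/2 m_i' A_i m_i + b_i' m_i   (m_i = X_i beta)
    """
    P0 = subject_prior.precision()
    mu0 = subject_prior.mean
    terms = []
    sign0, ld_P0 = np.linalg.slogdet(P0)
    sign_b, ld_Pb = np.linalg.slogdet(Pi_b)
    for est in posteriors:
        Pq = est.belief.precision()
        muq = est.belief.mean
        Prq = Pq + Pi_b - P0
        Prq = 0.5 * (Prq + Prq.T)
        np.linalg.cholesky(Prq)  # raises if the hierarchy is inconsistent
        Mi = np.linalg.inv(Prq)
        k = Pq @ muq - P0 @ mu0
        A = Pi_b - Pi_b @ Mi @ Pi_b
        b = Pi_b @ Mi @ k
        _, ld_Prq = np.linalg.slogdet(Prq)
        _, ld_Pq = np.linalg.slogdet(Pq)
        const = 0.5 * (ld_Pb - ld_P0 + ld_Pq - ld_Prq) + 0.5 * (
            k @ Mi @ k - muq @ Pq @ muq + mu0 @ P0 @ mu0)
        terms.append((0.5 * (A + A.T), b, float(const)))
    return terms


def _beta_posterior(terms, X, beta_prior):
    """Closed-form posterior over the stacked effects and the log evidence
    of the second level (integrating beta out)."""
    n_sub, n_cov = X.shape
    p = beta_prior.dim
    d = n_cov * p
    P_pr = np.kron(np.eye(n_cov), beta_prior.precision())
    m_pr = np.tile(beta_prior.mean, n_cov)
    Q = P_pr.copy()
    c = P_pr @ m_pr
    const = -0.5 * m_pr @ P_pr @ m_pr
    for i, (A, b, a) in enumerate(terms):
        xi = X[i]
        Q += np.kron(np.outer(xi, xi), A)
        c += np.kron(xi, b)
        const += a
    Q = 0.5 * (Q + Q.T)
    mu = np.linalg.solve(Q, c)
    cov = np.linalg.inv(Q)
    _, ld_Ppr = np.linalg.slogdet(P_pr)
    _, ld_Q = np.linalg.slogdet(Q)
    F = const + 0.5 * (c @ mu) + 0.5 * (ld_Ppr - ld_Q)
    return GaussianBelief(mu, 0.5 * (cov + cov.T)), float(F)


def fit_peb(subject_posteriors: list[PosteriorEstimate],
            subject_prior: GaussianBelief,
            peb: PEBModel | None = None) -> GroupPosterior:
    """Fit the hierarchical model over subject posteriors.

    Returns the posterior over group effects, the selected between-subject
    log-scaling gamma_b, and the (maximised) second-level free energy.
    Permuting the subject order leaves the result unchanged.
    """
    if len(subject_posteriors) < 2:
        raise ValueError("need at least 2 subjects")
    dims = {est.belief.dim for est in subject_posteriors}
    if dims != {subject_prior.dim}:
        raise ValueError("subject posterior dimensions differ from the prior")
    if peb is None:
        peb = PEBModel.group_mean(len(subject_posteriors), subject_prior)
    X = peb.design_matrix
    if X.shape[0] != len(subject_posteriors):
        raise ValueError("design matrix rows must match the subjects")

    def evaluate(gamma):
        Sigma_b = np.exp(gamma) * peb.base_between_cov
        Pi_b = np.linalg.inv(Sigma_b)
        terms = _subject_terms(subject_posteriors, subject_prior, Pi_b)
        belief, F = _beta_posterior(terms, X, peb.beta_prior)
        return belief, F

    cache: dict[float, tuple] = {}

    def eval_cached(gamma):
        g = float(gamma)
        if g not in cache:
            try:
                cache[g] = evaluate(g)
            except np.linalg.LinAlgError:
                cache[g] = (None, -np.inf)
        return cache[g]

    grid = np.asarray(peb.gamma_grid, float)
    best = max(grid, key=lambda g: eval_cached(g)[1])
    step = np.diff(grid).mean() if grid.size > 1 else 1.0
    for _ in range(peb.n_refinements):
        step /= 4.0
        local = best + step * np.arange(-3, 4)
        best = max(local, key=lambda g: eval_cached(g)[1])
    belief, F = eval_cached(best)
    return GroupPosterior(beta_belief=belief, gamma_b=float(best),
                          second_level_f=F, n_subjects=X.shape[0],
                          n_covariates=X.shape[1])


def peb_model_search(group: GroupPosterior, peb: PEBModel,
                     spec: NetworkSpec) -> ModelSpaceResult:
    """Bayesian model reduction over the group-mean effects.

    Enumerates the switchable-connection space at the second level and
    scores it against the group posterior, exactly as at the first level.
    Only the group-mean column is searched.
    """
    if group.n_covariates != 1:
        raise NotImplementedError("model search is defined over the "
                                  "group-mean column only")
    fake_fit = PosteriorEstimate(
        belief=group.beta_belief, noise=None, free_energy=group.second_level_f,
        n_iterations=0, converged=True)
    space = enumerate_model_space(spec, peb.beta_prior)
    return score_model_space(fake_fit, peb.beta_prior, space, spec)
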