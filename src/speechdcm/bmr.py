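"""Bayesian model reduction over nested shrink-prior models.

Given a model fitted once under a full prior, the posterior and evidence of
any model whose prior is a shrunk version of the full prior follow in
closed form.  Writing precisions Pi = Sigma^-1 with subscripts 0 (full
prior), q (full posterior) and tildes for the reduced counterparts:

    Pi~_q  = Pi_q + Pi~_0 - Pi_0
    mu~_q  = Pi~_q^-1 (Pi_q mu_q + Pi~_0 mu~_0 - Pi_0 mu_0)
    dF     = 1/2 [ln det Pi~_0 - ln det Pi_0 + ln det Pi_q - ln det Pi~_q]
           + 1/2 [mu~_q' Pi~_q mu~_q - mu_q' Pi_q mu_q
                  - mu~_0' Pi~_0 mu~_0 + mu_0' Pi_0 mu_0]

which is the log evidence of the reduced model relative to the full one.
Connections are switched off by shrinking their prior variance to 1e-8
around 0 (exact zeros would break the determinants).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .invert import GaussianBelief, PosteriorEstimate
from .model import NetworkSpec

__all__ = [
    "ReducedModel", "ModelSpaceResult", "bayesian_model_reduce",
    "enumerate_model_space", "score_model_space", "SHRINK_VARIANCE",
    "ReductionError",
]

SHRINK_VARIANCE = 1.0e-8
MAX_SWITCHABLE = 16


class ReductionError(RuntimeError):
    """The reduced posterior precision was not positive definite."""


@dataclass
class ReducedModel:
    """An on/off mask over the switchable connections with its prior."""

    mask: np.ndarray            # (n_switchable,) bool; True = present
    reduced_prior: GaussianBelief

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)


@dataclass
class ModelSpaceResult:
    """Scores over a reduced-model space plus per-connection summaries."""

    masks: np.ndarray           # (n_models, n_switchable) bool
    delta_f: np.ndarray         # (n_models,) evidence relative to full model
    probabilities: np.ndarray   # softmax of delta_f, uniform model priors
    switchable_pairs: tuple[tuple[int, int], ...]
    switchable_indices: np.ndarray   # position of each switchable pair in theta
    pp: np.ndarray              # (n_switchable,) presence probabilities
    bma_mean: np.ndarray        # (p,) model-averaged posterior mean
    best_index: int

    def connection_pp(self, spec: NetworkSpec, source, target) -> float:
        """Presence probability of one connection (1 for non-switchable)."""
        idx = spec.pair_index(source, target)
        pair = spec.extrinsic_pairs()[idx]
        if pair in self.switchable_pairs:
            return float(self.pp[self.switchable_pairs.index(pair)])
        return 1.0

    def connection_mean(self, spec: NetworkSpec, source, target) -> float:
        """Model-averaged posterior mean of one extrinsic rate (Hz)."""
        return float(self.bma_mean[spec.pair_index(source, target)])


def bayesian_model_reduce(full_prior: GaussianBelief,
                          full_posterior: GaussianBelief,
                          reduced_prior: GaussianBelief
                          ) -> tuple[GaussianBelief, float]:
    """Reduced posterior and log-evidence change for a shrunk prior."""
    if not (full_prior.dim == full_posterior.dim == reduced_prior.dim):
        raise ValueError("belief dimensions differ")
    P0 = full_prior.precision()
    Pq = full_posterior.precision()
    Pr0 = reduced_prior.precision()
    Prq = Pq + Pr0 - P0
    Prq = 0.5 * (Prq + Prq.T)
    try:
        np.linalg.cholesky(Prq)
    except np.linalg.LinAlgError:
        raise ReductionError("reduced posterior precision is not positive "
                             "definite; the reduction is too severe")
    r = Pq @ full_posterior.mean + Pr0 @ reduced_prior.mean - P0 @ full_prior.mean
    mu_rq = np.linalg.solve(Prq, r)
    ld = lambda Mat: np.linalg.slogdet(Mat)[1]
    delta_f = 0.5 * (ld(Pr0) - ld(P0) + ld(Pq) - ld(Prq)) + 0.5 * (
        r @ mu_rq
        - full_posterior.mean @ Pq @ full_posterior.mean
        - reduced_prior.mean @ Pr0 @ reduced_prior.mean
        + full_prior.mean @ P0 @ full_prior.mean
    )
    cov_rq = np.linalg.inv(Prq)
    return GaussianBelief(mu_rq, 0.5 * (cov_rq + cov_rq.T)), float(delta_f)


def _switchable_theta_indices(spec: NetworkSpec) -> np.ndarray:
    pairs = spec.extrinsic_pairs()
    return np.array([pairs.index(p) for p in spec.switchable_pairs()],
                    dtype=int)


def reduced_prior_for_mask(mask: np.ndarray, full_prior: GaussianBelief,
                           spec: NetworkSpec) -> GaussianBelief:
    """Full prior with absent switchable connections shrunk to ~0."""
    idx = _switchable_theta_indices(spec)
    cov = full_prior.cov.copy()
    mean = full_prior.mean.copy()
    off = idx[~np.asarray(mask, bool)]
    # zero the cross terms so the shrunk parameters decouple
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    cov[off, off] = SHRINK_VARIANCE
    mean[off] = 0.0
    return GaussianBelief(mean, cov)


def enumerate_model_space(spec: NetworkSpec,
                          full_prior: GaussianBelief) -> list[ReducedModel]:
    """All present/absent combinations over the switchable connections."""
    n_sw = len(spec.switchable_pairs())
    if n_sw > MAX_SWITCHABLE:
        raise ValueError(f"refusing to enumerate 2^{n_sw} models")
    space = []
    for bits in itertools.product([True, False], repeat=n_sw):
        mask = np.array(bits, bool)
        space.append(ReducedModel(mask, reduced_prior_for_mask(
            mask, full_prior, spec)))
    return space


def score_model_space(full_fit: PosteriorEstimate, prior: GaussianBelief,
                      space: list[ReducedModel],
                      spec: NetworkSpec) -> ModelSpaceResult:
    """Score every reduced model and average over the space.

    Model probabilities are softmax(dF) under uniform model priors; the
    presence probability of a connection is the summed probability of the
    models that retain it; the model-averaged mean weights each reduced
    posterior mean by its model probability.
    """
    n_models = len(space)
    p = prior.dim
    n_sw = space[0].mask.size
    masks = (np.stack([m.mask for m in space]) if n_sw
             else np.zeros((n_models, 0), bool))
    delta_f = np.empty(n_models)
    means = np.empty((n_models, p))
    for k, model in enumerate(space):
        post, df = bayesian_model_reduce(prior, full_fit.belief,
                                         model.reduced_prior)
        delta_f[k] = df
        means[k] = post.mean
    z = delta_f - delta_f.max()
    probabilities = np.exp(z) / np.exp(z).sum()
    pp = probabilities @ masks if masks.shape[1] else np.zeros(0)
    bma_mean = probabilities @ means
    return ModelSpaceResult(
        masks=masks,
        delta_f=delta_f,
        probabilities=probabilities,
        switchable_pairs=spec.switchable_pairs(),
        switchable_indices=_switchable_theta_indices(spec),
        pp=pp,
        bma_mean=bma_mean,
        best_index=int(np.argmax(delta_f)),
    )
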