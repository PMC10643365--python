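# Methods

`speechdcm` implements a complete effective-connectivity analysis for a
four-region auditory speech repetition network — A1 (primary auditory
cortex), pSTS (posterior superior temporal sulcus, a Wernicke-area proxy),
pOp (pars opercularis, a Broca-area proxy, dorsal or ventral subregion) and
M1 (primary motor cortex, face or tongue/larynx subregion) — from regional
BOLD time series. The package ships no fMRI recordings: a seeded
synthetic-cohort generator with known ground truth stands in for them,
and every stage of the pipeline is exercised and validated against that
ground truth.

## Forward (generative) model

**Architecture.** All 16 ordered region pairs are connected except
A1 → M1, giving 15 connections of which 4 are self-connections. Auditory
input drives A1 only. The four subregional configurations (dpOp/vpOp ×
M1-f/M1-tl) share this architecture and differ only in which anatomical
subregion supplied the time series.

**Neural dynamics.** Deterministic linear state equation

    dx/dt = A x + C u

with no bilinear term: the model estimates *average* effective
connectivity over a run, not condition-specific modulation. Extrinsic
(between-region) entries of `A` are rate constants in Hz. Self-connections
are parameterised as `-0.5 * exp(s_i)` Hz, so the prior mean `s_i = 0`
yields the default −0.5 Hz, positivity of `s_i` means *greater*
self-inhibition, and the system is exponentially stable a priori. `u` is a
unit-height box-car over stimulation blocks on a microtime grid of 16 bins
per TR (event-level input at 2.5 s ISI is available for sensitivity
analyses but off by default — at this block density the box-car is an
adequate envelope). Each microtime bin is advanced *exactly* with the
augmented-matrix exponential (input held constant within a bin); the test
suite verifies agreement with a fine-step RK4 oracle to 1e−6.

**Haemodynamics.** Standard balloon–Windkessel model per region:

    s' = x − κ s − γ (f − 1)
    f' = s
    τ v' = f − v^{1/α}
    τ q' = f (1 − (1 − E0)^{1/f}) / E0 − v^{1/α} q / v
    y = S · V0 · (k1 (1 − q) + k2 (1 − q/v) + k3 (1 − v))

with constants κ0 = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ0 = 2.0 s, α = 0.32,
E0 = 0.4, V0 = 0.04 and 3 T BOLD coefficients k1 = 4.3·ν0·E0·TE
(ν0 = 40.3 s⁻¹), k2 = ε·r0·E0·TE (r0 = 25 s⁻¹, ε = 1), k3 = 1 − ε at
TE = 30 ms. Per-region log-scalings of κ and τ are estimated; everything
else is fixed. The ODEs are integrated by RK4 on the microtime grid with
the neural drive held constant per bin.

**Observation units.** `S = 500`, i.e. the output is 5 × percent signal
change. The unit is deliberate: the inversion's noise hyperprior centres
each region's log-precision on zero ("noise variance 1"), which is only
meaningful if typical measurement noise actually sits near unit variance
on the model's output scale. With `S = 500`, block responses of this
network land at amplitude ≈ 3–5 and 25% measurement noise at ≈ unit sd —
the same convention as rescaling data to a maximum of ~4 before inversion,
as SPM does. Because generator and inversion share the forward model, the
choice cancels in data space; it matters only for how informative the
noise hyperprior is.

**Balloon-model domain.** Under sustained neural drive `x`, inflow
equilibrates at `f* = 1 + x/γ`; sustained deactivation below −γ = −0.32
therefore has no positive-inflow equilibrium and the model leaves its
domain. The driving gain of the synthetic cohorts (0.15) keeps neural
excursions within this range, and the generator's stability screen runs
the full forward integration (not just an eigenvalue check), resampling
pathological draws. During inversion, candidate steps whose integration
fails are treated as rejected.

**Sampling.** Predictions are decimated at end-of-volume times
t = TR, 2·TR, … and mean-centred per region; mean-centring is the only
confound handling (no drift regressors). TR is taken as 3.085 s, 66
volumes per run (descriptions of this acquisition also round the TR to
3080 ms; 3.085 s is adopted here and is configurable).

## Variational Laplace inversion

Fixed-form Gaussian variational Bayes maximising

    F = ⟨ln p(y|θ)⟩_q − KL(q(θ) ‖ p(θ)) − penalty(λ)

with the expected log-likelihood under the usual local linearisation,
`ln p(y|μ) − ½ tr(Σ Jᵀ Π J)`. On a linear forward model the fixed point is
the exact conjugate posterior and F equals the log marginal likelihood;
the test suite asserts this to 1e−6 relative.

- **Priors** (zero mean throughout): extrinsic rates variance 1/4 (sd
  0.5 Hz, >95% of mass in ±1 Hz), self-connection log-scalings 1/16,
  input gain 1, haemodynamic log-scalings 1/64. Noise: one log-precision
  λ_r per region, i.i.d. within region, Gaussian hyperprior mean 0,
  variance 1/8.
- **Optimisation**: Gauss–Newton/Levenberg–Marquardt ascent on F.
  Jacobian by central finite differences, step `1e-3 · max(1, |θ_i|)`, one
  batched forward pass (the compiled integrator is batched over parameter
  vectors, so a 24-parameter Jacobian costs a single pass). Marquardt
  damping starts at 1/8, ×2 on a rejected step, ×0.5 on acceptance.
  λ is updated after each accepted step by guarded Newton ascent on F.
- **Convergence**: four consecutive steps whose free-energy change is
  below 0.01 nats (accepted steps, or rejected ones whose shortfall is
  below tolerance — near the optimum proposals are rejected for
  numerically negligible deficits); hard cap 64 iterations. Accepted-step
  traces are non-decreasing by construction and asserted in the tests.
- The simplified i.i.d. noise model (no serial correlations) matches the
  white noise the generator produces; see limitations.

## Bayesian model reduction

Posteriors and evidence of any model whose prior shrinks the full prior
follow in closed form (precisions Π, tildes = reduced):

    Π̃_q = Π_q + Π̃_0 − Π_0
    μ̃_q = Π̃_q⁻¹ (Π_q μ_q + Π̃_0 μ̃_0 − Π_0 μ_0)
    ΔF  = ½[ln|Π̃_0| − ln|Π_0| + ln|Π_q| − ln|Π̃_q|]
        + ½[μ̃_qᵀΠ̃_qμ̃_q − μ_qᵀΠ_qμ_q − μ̃_0ᵀΠ̃_0μ̃_0 + μ_0ᵀΠ_0μ_0]

verified against exact conjugate evidence differences to 1e−8. Switched-off
connections get shrink variance 1e−8 around zero (exact zeros would break
the determinants). The default switchable set is the 8 extrinsic
connections excluding the three afferents of A1 — self-connections are
never switched — giving the 2⁸ = 256-model space used throughout. The rationale: input-side
connections into A1 are anatomically obligatory, while every other
extrinsic route is a live hypothesis; the choice is configurable via
`NetworkSpec.switchable_mask` if a different family structure is wanted.
Model probabilities are softmax(ΔF) under
uniform model priors; a connection's presence probability Pp is the summed
probability of models retaining it; model-averaged means weight each
reduced posterior by its model probability.

## Parametric empirical Bayes

Second level: θ_i = X_i β + ε_i, ε_i ~ N(0, Σ_b), default design a single
column of ones (group mean). Σ_b = exp(γ_b) · diag(first-level prior
covariance)/16 — one between-subject log-scaling, not per-parameter
(identifiable at desk-scale cohorts). Each subject's contribution is
re-weighted from its fitted prior to the empirical prior N(X_iβ, Σ_b)
using the same algebra as model reduction, which makes the β posterior and
the integrated second-level free energy closed-form for fixed γ_b; γ_b is
maximised on a coarse grid (−4…4, 17 points) with three local refinement
rounds (the incumbent is always retained, so refinement never lowers F).
Second-level priors equal first-level priors. Word and pseudoword runs are
estimated and aggregated entirely separately. Group-level model search
re-uses the 256-model reduction on the β posterior.

## Degeneracy taxonomy

Per fitted model, the two afferents of M1 are summarised by their
model-averaged mean and Pp; "excitatory" = mean > 0 **and** Pp strictly
greater than 0.75 (a tie at 0.75 does not count). Groups: A both afferents
excitatory, B only pSTS → M1, C only pOp → M1, D neither — D therefore
includes decisively *inhibitory* afferents, since the taxonomy keys on
excitation only. A model is consistent with the classical serial account
iff it is Group C with excitatory pSTS → pOp. Whether the excitatory
criterion should use model-averaged or full-model means is not fixed by
the source analysis; model-averaged is the default here (full-model means
are available from the posterior directly). Within-subject variability is
the Shannon entropy (nats) of the empirical group-membership distribution
per subject and task across configurations (an across-task variant can be
computed from the same label table). Task differences in per-subject group
counts use two-sided Mann–Whitney–Wilcoxon tests, Bonferroni-corrected ×4.

## Synthetic cohorts

The generator emulates the repetition experiment: runs of 66 volumes at
TR 3.085 s; 4 blocks of 10 stimuli (25 s per block, ISI 2.5 s)
interleaved with 16 s rest, the run opening with rest (block onsets 16,
57, 98, 139 s); word and pseudoword tasks share timing and differ in
stimulus duration (0.65 s vs 1.45 s, used by the event-level input mode).
Subjects are drawn from four architectural archetypes mirroring the
taxonomy (A/B/C/D at mixture 0.55/0.20/0.05/0.20 by default); the backbone
rates are group-level word-repetition magnitudes (excitatory A1 efferents
≈ 0.4–0.5 Hz, pSTS → M1 = 0.66, pOp → M1 = 0.31, mutually inhibitory
pSTS ↔ pOp ≈ −0.2…−0.3, inhibitory M1 feedback). Archetype-absent M1
afferents are clamped to exactly zero so ground-truth labels stay crisp;
all other extrinsic rates receive Gaussian between-subject deviations
(sd 0.1 Hz), per-configuration jitter (sd 0.05 Hz) and small self/
haemodynamic log-scaling variation (sd 0.05). The jitter places
borderline cells near the excitatory threshold, so cohorts exhibit
non-zero membership entropy by construction. Measurement noise is white
Gaussian, sd = 0.25 × each region's noiseless signal sd by default.
Everything is deterministic given the seed.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: serially correlated physiological noise,
scanner drift, motion residuals, regional HRF mis-specification beyond
log-scaled κ/τ, peak-voxel selection variability, and any behavioural
coupling. The white-noise choice deliberately matches the inversion's
i.i.d. noise model, so recovery results quantify the pipeline's internal
consistency, not robustness to noise-model mismatch.

## Problem sizes

Desk-scale cohorts are used throughout: the recovery suite inverts 12
subjects × 2 tasks × 2 configurations at 25% noise (48 inversions,
~1 minute total) plus a 12-subject single-configuration cohort for the
group-level recovery of a planted +0.5 Hz pSTS → M1 effect; the demo
analysis under `analysis/` uses the same shape. The study-scale cohort
(59 subjects, 4 configurations, both tasks) runs through the identical
code path and is a configuration change.

## Known limitations

- The two afferents of M1 are driven by strongly correlated upstream time
  courses under a block design, so their individual rates are partly
  collinear; at 25% noise a minority of archetype-A cells are reported as
  B or C. This is a genuine identifiability feature of the design (and
  the package's topic), not an optimiser artefact: the variational
  optimum can exceed the free energy at the generating parameters.
- Model reduction is exact only when the reduced posterior is a
  reweighting of the full one; large posterior shifts make ΔF
  approximate (documented tolerance ~1 nat against refits).
- A single between-subject scaling γ_b cannot express parameter-specific
  heterogeneity.
- The i.i.d. noise model omits serial correlations; with real fMRI
  residuals the posterior probabilities would be optimistic.
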