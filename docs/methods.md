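# Methods

## Discretization and probability conventions

All inference lives on a regular grid over a 1-D or 2-D latent space,
by default [−5, 5] per axis. Distributions are stored as probability
*mass* vectors (density × cell measure), so normalization is exact and
entropy/KL are computed in mass units: a uniform field on n cells has
entropy log n, and the entropy regularizer for a uniform prior contributes
exactly −λ log n to the loss. Three resolutions are bundled: 21 bins/dim
(test profile), 41 (scaled experiments), and 85 (the full configuration;
7225 cells). Because the dense cell-pair covariance at 85 bins is a
7225 × 7225 matrix, the variance-fraction statistic is also available in a
streaming form, var(P u)/Σᵢ var(Pᵢ) over stored posterior draws, which
never materializes the matrix; the two agree to rounding on shared draws.

## World models

The experimenter maps a scalar stimulus s (uniform on [−3, 3] during
learning, or a three-atom sub-threshold ensemble {−Δs, 0, +Δs} with
zero-signal probability p0) to 2-D observations **E** through a Gaussian
whose mean carries the stimulus (mean (s, (s+s³)/10), constant covariance
0.5 I) or whose covariance carries it (zero mean; 0.5 I + tanh(s) Σ₊ for
s > 0 and 0.5 I − tanh(s) Σ₋ for s ≤ 0 with Σ± = [[1, ±1], [±1, 1]]).
A `custom` mode accepts arbitrary mean/covariance functions; the
deterministic (zero-covariance) limit returns the mean exactly, which the
sub-threshold analyses use as their noiseless observation model.
The brain assumes **E** = **x** + isotropic Gaussian noise with per-axis
variance σ_E² — 0.04 ("precise") or 0.36 ("imprecise") — and carries a
prior mass vector on the shared grid.

## Prior learning

The objective is KL(p_e(**E**) ‖ p_b(**E**)) − λ H(p_b(**x**)) with
λ = 10⁻³, where p_b(**E**) = Σ_x p_b(**x**) p_b(**E**|**x**) by grid
quadrature. The log-prior gradient of the KL term is the negative average
posterior over **E** ~ p_e(**E**); the entropy term adds
λ p(1 + log p). Two estimators of the average posterior are provided:
fresh Monte-Carlo draws of (s, **E**) per iteration (default, 1000 draws)
and a deterministic quadrature over the evidence grid; a frozen-sample mode
supports gradient checking, and the analytic gradient matches central
differences of the frozen-sample loss to relative error below 10⁻⁴.

One numerical point matters. Taken literally, "step the log prior along
the gradient, then renormalize" is a winner-take-all instability: because
the unconstrained log-space gradient at the self-consistent optimum equals
−p (not a constant), the raw iteration drifts toward mass concentration
and, at every resolution we tested (21–85 bins), collapses the prior to a
single cell within the 300-iteration schedule while the KL rises again.
Enforcing the simplex constraint *as part of the step* — moving along the
tangent projection g − p ⟨g, 1⟩, the pullback gradient of the softmax
parameterization — makes the self-consistent prior a genuine fixed point
and yields monotone KL descent. The projected update is the default;
`learn_prior(..., projected_gradient=False)` retains the literal variant.
The schedule is the stated one: initial step 100, halved every 100
iterations, 300 iterations, prior renormalized every step with a 10⁻¹²
mass floor. The per-iteration KL trace is a Monte-Carlo density-ratio
estimate at the sampled observations (p_e(**E**) evaluated by s-quadrature);
the trace also records the total-variation distance between the prior and
the iteration's average posterior, the self-consistency residual, which
falls over training in all four task conditions.

## Posterior derivatives and the sub-threshold analysis

dp/ds is a central finite difference of noise-averaged posteriors at
s = ±Δs (Δs = 0.01 by default), averaging over observation noise. Two
noise designs are implemented: common random numbers across the two sides
(`paired=True`, the low-variance estimator) and independent draw sets
(`paired=False`, the design described for the original experiments). The
distinction is consequential — see "Posterior-noise filtering" below.
dp/dπ is available as a central finite difference over π (step 0.01,
matching the Δs scale), as the exact derivative of the normalized posterior
(quotient rule), and as the simplified likelihood × [p₁ − p₂] form that is
exact when zero-signal evidence is equally likely under both categories.

`subthreshold_analysis` builds everything for one delta-mixture ensemble
from a single observation-noise stream: per-atom noise-averaged posteriors,
the self-consistent prior (fixed-point iteration of prior ← average
posterior on cached likelihood rows), the category priors, dp/ds, and the
noise-averaged analytic dp/dπ. Sharing the stream is essential: at
Δs = 0.01 the stimulus signal is O(Δs), and with independent noise streams
the Monte-Carlo error of the two averages dominates the comparison of the
two derivative directions. With zero observation noise the symmetry cosine
exceeds 0.99 at (Δs, p0) = (0.01, 0.9) and degrades as Δs grows; the p0
dependence is far weaker than the Δs dependence in this implementation.
Note the zero-noise fixed point degenerates for large Δs (repeated
conditioning on a fixed likelihood concentrates the prior), so noiseless
sub-threshold analyses are meaningful only for small category offsets.
A 1-D Gaussian-mixture observer (categories at ±μ_x, Gaussian stimulus
noise) provides a closed-form cross-check: its cosine rises monotonically
toward 1 as μ_x → 0.

Category convention: category 1 corresponds to s > 0 throughout, which
makes the reported cosines positive; swapping labels flips the sign of
dp/dπ, as a test asserts.

## Posterior-noise filtering (the four-condition experiment)

For each of the four conditions (mean- vs covariance-coded observations ×
precise vs imprecise likelihood), the experiment learns a prior, then
evaluates u'Σ_p u / tr Σ_p — the fraction of zero-signal posterior-density
variance along the unit dp/ds direction — under the uniform (pre-learning)
and learned priors, using the same 2000-draw zero-signal observation set
for both, repeated 4 times. The filtering factorization
Σ_p ∝ diag(p) Σ_LH diag(p) is validated separately: in a small-noise regime
its top eigenvector agrees with the empirical Σ_p top eigenvector to within
a 10° principal angle.

Findings at our scales: the fraction increases strongly for mean-coded ×
imprecise, and weakly for the two precise conditions (a precise likelihood
attenuates any effect of the prior). The covariance-coded × imprecise
condition is delicate. With the paired (common-random-numbers) dp/ds
estimator the fraction *increases* slightly at every resolution tested;
with the unpaired estimator the direction estimate contains a Monte-Carlo
noise component that is relatively large in this condition (the covariance
signal at Δs = 0.01 is tiny) and aligns preferentially with the dominant
posterior-variability directions of the pre-learning model, which can
produce an apparent slight *decrease*. The experiment driver uses the
unpaired estimator with 1000 draws per side (the stated design); the sign
of the covariance × imprecise change remains seed-dependent at 21–85 bins
in our implementation, and we report it as such rather than fixing a seed
that produces one outcome.

## Distributional codes and session statistics

Codes map a mass vector to mean spike counts: Voronoi-binned latent
sampling (k = 20 samples/trial) and a Gaussian-bump linear readout are
mixture-linear (LDCs); a squared readout and a floored log-mass
(natural-parameter) readout are not. All kinds add an affine baseline and
emit Poisson counts. The mixture gap E S(mixture) − mixture of E S is
computed exactly from mean rates (identically zero for linear kinds) or
estimated by Monte Carlo with per-neuron standard errors; the constructed
bimodal-vs-unimodal pair separates the two classes by > 5 SE.

Tuning curves average mean rates over observation noise with a shared
noise stream across stimulus values; f′ is a central difference at s = 0
and σ the response SD there, giving d′ = f′/σ. Choice probability uses the
rank-statistic (Mann–Whitney) ROC area with midrank ties, invariant to
monotone response transforms; a brute-force pairwise-comparison oracle
checks it.

The canonical belief-feedback session (`belief_feedback_demo`) is a coarse
two-category task on a *straight* discrimination axis E(s) = (s, 0) with
observation noise 0.5 I during learning and an imprecise likelihood, whose
category priors are the self-consistent noise-averaged posteriors at
s = ±1.5 (p0 = 0.2). Sessions run at s = 0 with no shared observation
noise — pure belief feedback plus private Poisson spiking — through a
128-neuron linear-moment code (gain 1600, baseline 0.5, bump width 0.5).
Two design points are deliberate: belief feedback is only visible when the
likelihood is broad enough for the prior to move the posterior (a precise
likelihood at widely separated category priors yields essentially no
modulation), and a straight stimulus axis is required for tight
f′-alignment — on the cubic axis the ±1.5 category chord bends away from
the local tangent and caps the belief/f′ cosine near 0.988.

## V1 belief spectrum

The sparse-coding model: images y = A z + pixel noise (SD 0.4), with
unit-norm oriented-grating projective fields (16 × 16 patch, 2 cycles,
Gaussian envelope SD 0.2 patch widths) for n neurons tiling [0°, 180°).
Intensities are nonnegative with exponential priors whose mean is
0.2 + 1.0 · bump(8°) around the grating hypothesis G currently entertained;
G ranges over {0°, 90°, 45°, 135°}, grouped into cardinal and oblique
contexts. The session's true context is cardinal; the pre-trial cue reports
it with probability 0.8, and the observer weights the cued context's
gratings accordingly. Inference is Gibbs sampling — truncated-normal
conditional updates of all intensities (all trials advanced in parallel)
and a categorical resample of G per sweep — with 10 burn-in and 20 retained
sweeps; the response is each neuron's summed intensity samples, so doubling
the retained sweeps doubles mean counts.

Zero-signal trials show white noise (SD 0.5). The noise-correlation matrix
is eigendecomposed and component significance assessed by parallel
analysis: component k is significant if its eigenvalue exceeds the 95th
percentile of the k-th eigenvalue over 100 per-neuron trial shuffles,
counting from the top; the count is also reported at the 90th/99th
percentiles and against a max-eigenvalue floor. Belief components are
identified by cosine similarity (threshold 0.8) with each task's response
template — the finite difference of mean responses between the context's
two discriminanda, which matches the eigenvector point-spread better than
an analytic bump-difference and satisfies the balanced/orthogonal/
sign-flip properties expected of a task axis. Remaining significant
components with a predominantly single-frequency sinusoidal profile in
preferred orientation are labelled stimulus-driven; with the context
modulation switched off the significant spectrum is entirely sinusoidal
and arrives in near-degenerate quadrature pairs. At the reference scale
(256 neurons, 2000 trials) the spectrum has five significant components:
the two task axes (|cosine| ≈ 0.93 and 0.87) and three stimulus-driven
components; the count is stable across the reported significance criteria
but, like any shuffle-floor count, grows with trial count. Raising cue
reliability toward 1 drives the miscued task's eigenvalue toward the
shuffle floor.

## Scales, determinism, and limitations

Default problem sizes (41-bin experiments, 1000 draws per learning
iteration, 2000 covariance draws, 2 × 10⁴ session trials, 256-neuron V1
sessions) were chosen so each analysis completes in minutes on one CPU;
the 85-bin configuration runs through the identical code path. Every
sampler takes a seed or generator and reruns byte-identically; experiment
drivers embed the config hash and seed in their outputs and `verify`
replays and diffs them. The learning loop evaluates likelihood rows in
single precision (the per-iteration average is insensitive to it); all
analytic gradients and statistics are double precision.

The synthetic worlds idealize real experiments in known ways: observation
noise is Gaussian and trial-independent, beliefs are i.i.d. symmetric
Beta draws with no serial dependence, spiking is Poisson with no shared
intrinsic covariability beyond what the model injects, and the V1 model is
a minimal sparse-coding instance rather than a fitted circuit. Passing
tests therefore demonstrate the internal consistency of the theory's
predictions under its own assumptions, not their quantitative fit to any
recorded dataset.
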