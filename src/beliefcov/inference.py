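"""Posterior computation, belief-conditioned priors, and their derivatives.

The central objects are the posterior over the latent x given an observation,

    p_b(x | E, pi)  propto  p_b(E | x) [pi p_b(x|C=1) + (1-pi) p_b(x|C=2)],

and its two perturbations at the category boundary: the change with a small
stimulus step (dp/ds, a finite difference of noise-averaged posteriors at
s = +/-ds) and the change with the categorical belief (dp/dpi).  For an
observer whose prior satisfies the self-consistency rule (prior = average
posterior over the task ensemble) these two directions in distribution space
become approximately proportional in the sub-threshold regime (small ds,
frequent zero-signal trials), which is what `proportionality_experiment`
quantifies as a cosine similarity.

Category convention: category 1 <-> s > 0 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import LatentGrid, ProbabilityField, cosine_similarity, total_variation
from .world import (
    BrainModel,
    ExperimenterModel,
    experimenter_mean,
    likelihood_field,
    likelihood_values,
    sample_observation,
)

__all__ = [
    "BeliefState",
    "PosteriorDerivative",
    "TaskPriors",
    "posterior",
    "category_prior",
    "belief_prior",
    "posterior_given_belief",
    "task_priors",
    "self_consistent_prior",
    "average_posterior",
    "dposterior_ds",
    "dposterior_dpi",
    "alignment",
    "proportionality_experiment",
    "category_decoder",
    "gaussian_mixture_demo",
]

_DERIV_SUM_TOL = 1e-8


@dataclass(frozen=True)
class BeliefState:
    """Scalar belief pi = p_b(C=1 | ...) in [0, 1]."""

    pi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("belief pi must lie in [0, 1]")


@dataclass
class PosteriorDerivative:
    """Signed per-cell change of a normalized posterior.

    ``wrt`` is "s" or "pi"; ``step`` is the finite-difference step used
    (0 for analytic forms).  Entries sum to zero because the derivative of a
    normalized mass vector is mean-free.
    """

    grid: LatentGrid
    delta_mass: np.ndarray
    wrt: str
    step: float

    def __post_init__(self) -> None:
        self.delta_mass = np.asarray(self.delta_mass, dtype=float)
        scale = max(np.abs(self.delta_mass).sum(), 1.0)
        if abs(self.delta_mass.sum()) > _DERIV_SUM_TOL * scale:
            raise ValueError("derivative of a normalized mass must sum to 0")

    def unit(self) -> np.ndarray:
        n = np.linalg.norm(self.delta_mass)
        if n == 0:
            raise ValueError("zero derivative has no direction")
        return self.delta_mass / n


@dataclass
class TaskPriors:
    """Per-category priors p_b(x|C=1), p_b(x|C=2) on a shared grid."""

    p1: ProbabilityField
    p2: ProbabilityField

    def __post_init__(self) -> None:
        if self.p1.grid != self.p2.grid:
            raise ValueError("category priors must share a grid")

    def marginal(self, pi: float = 0.5) -> ProbabilityField:
        return belief_prior(pi, self.p1, self.p2)


def posterior(prior: ProbabilityField, lik: ProbabilityField) -> ProbabilityField:
    """Bayes' rule on the grid: mass propto prior * likelihood, normalized."""
    if prior.grid != lik.grid:
        raise ValueError("prior and likelihood live on different grids")
    product = prior.mass * lik.mass
    total = product.sum()
    if total <= 0:
        raise ValueError("impossible evidence: prior x likelihood is zero everywhere")
    return ProbabilityField(prior.grid, product / total, normalized=True)


def _posterior_rows(prior_mass: np.ndarray, lik_rows: np.ndarray) -> np.ndarray:
    """Row-wise posteriors for a batch of likelihood vectors."""
    prod = lik_rows * prior_mass[None, :]
    totals = prod.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("impossible evidence in a batch row")
    return prod / totals


def average_posterior(
    brain: BrainModel,
    exp: ExperimenterModel,
    s_values: np.ndarray,
    weights: np.ndarray,
    n_draws: int,
    rng: np.random.Generator | int,
    prior: ProbabilityField | None = None,
) -> ProbabilityField:
    """Weighted noise-averaged posterior over a discrete set of stimuli.

    For each stimulus value, ``n_draws`` observations are drawn from
    p_e(E|s) and the posteriors under ``prior`` (default: the brain's prior)
    are averaged; a deterministic observation model (zero covariance)
    contributes its single exact posterior.
    """
    rng = np.random.default_rng(rng)
    prior = prior if prior is not None else brain.prior
    acc = np.zeros(brain.grid.n_cells)
    for s_k, w_k in zip(np.atleast_1d(s_values), np.atleast_1d(weights)):
        if w_k == 0:
            continue
        deterministic = np.allclose(exp.cov(s_k), 0)
        draws = 1 if deterministic else n_draws
        E = sample_observation(exp, float(s_k), rng, size=draws)
        rows = _posterior_rows(prior.mass, likelihood_values(brain, E))
        acc += w_k * rows.mean(axis=0)
    return ProbabilityField(brain.grid, acc).normalize()


def category_prior(
    brain: BrainModel,
    exp: ExperimenterModel,
    c: int,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    prior: ProbabilityField | None = None,
) -> ProbabilityField:
    """Self-consistency prior for one category: average posterior over
    s ~ p_e(s|C=c) and E ~ p_e(E|s).

    For the delta-mixture ensemble the stimulus average is an exact weighted
    sum over the atoms; for the uniform ensemble both s and E are sampled.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng)
    ens = exp.stimulus_dist
    if ens.kind == "delta_mixture":
        s_vals, w = ens.category_atoms(c)
        return average_posterior(brain, exp, s_vals, w, n_draws, rng, prior=prior)
    lo, hi = ens.bounds
    s_draws = rng.uniform(0 if c == 1 else lo, hi if c == 1 else 0, size=n_draws)
    return average_posterior(
        brain, exp, s_draws, np.full(n_draws, 1.0 / n_draws), 1, rng, prior=prior
    )


def belief_prior(
    pi: float, p1: ProbabilityField, p2: ProbabilityField
) -> ProbabilityField:
    """Graded mixture of the two category priors: pi p1 + (1 - pi) p2."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError("belief pi must lie in [0, 1]")
    if p1.grid != p2.grid:
        raise ValueError("category priors must share a grid")
    mass = pi * p1.mass + (1.0 - pi) * p2.mass
    return ProbabilityField(p1.grid, mass, normalized=p1.normalized and p2.normalized)


def posterior_given_belief(
    brain: BrainModel, E: np.ndarray, pi: float, priors: TaskPriors
) -> ProbabilityField:
    """Posterior over x given an observation and a graded category belief."""
    return posterior(belief_prior(pi, priors.p1, priors.p2), likelihood_field(brain, E))


def task_priors(
    brain: BrainModel,
    exp: ExperimenterModel,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    prior: ProbabilityField | None = None,
) -> TaskPriors:
    rng = np.random.default_rng(rng)
    return TaskPriors(
        p1=category_prior(brain, exp, 1, n_draws, rng, prior=prior),
        p2=category_prior(brain, exp, 2, n_draws, rng, prior=prior),
    )


def self_consistent_prior(
    brain: BrainModel,
    exp: ExperimenterModel,
    n_iter: int = 60,
    n_draws: int = 500,
    rng: np.random.Generator | int = 0,
    tol: float = 1e-10,
) -> ProbabilityField:
    """Fixed point of the self-consistency map prior <- E[posterior].

    Iterates the average posterior over the full stimulus ensemble starting
    from the brain's current prior.  With a deterministic observation model
    and a delta-mixture ensemble the iteration is exact; otherwise the same
    Monte-Carlo noise stream is reused so the map is deterministic given rng.
    """
    rng = np.random.default_rng(rng)
    ens = exp.stimulus_dist
    if ens.kind == "delta_mixture":
        s_vals, w = ens.atoms()
    else:
        s_vals = rng.uniform(*ens.bounds, size=n_draws)
        w = np.full(n_draws, 1.0 / n_draws)
    noise_seed = int(rng.integers(2**31))  # frozen E stream -> deterministic map
    prior = brain.prior
    for _ in range(n_iter):
        nxt = average_posterior(
            brain, exp, s_vals, w, n_draws,
            np.random.default_rng(noise_seed), prior=prior,
        )
        done = total_variation(nxt, prior) < tol
        prior = nxt
        if done:
            break
    return prior


def dposterior_ds(
    brain: BrainModel,
    exp: ExperimenterModel,
    delta_s: float = 0.01,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    prior: ProbabilityField | None = None,
    paired: bool = True,
) -> PosteriorDerivative:
    """Finite-difference stimulus derivative of the noise-averaged posterior.

    (mean posterior at +delta_s - mean posterior at -delta_s) / (2 delta_s),
    averaging over observation noise E ~ p_e(E | +/-delta_s).

    With ``paired=True`` the same observation-noise stream is applied at
    both stimulus values (common random numbers), so the finite difference
    isolates the stimulus effect; ``paired=False`` draws the two noise sets
    independently, leaving a Monte-Carlo noise component in the direction
    whose relative size grows as the stimulus signal shrinks.
    """
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    rng = np.random.default_rng(rng)
    seeds = {+1: int(rng.integers(2**31)), -1: int(rng.integers(2**31))}
    if paired:
        seeds[-1] = seeds[+1]
    sides = {}
    for sign in (+1, -1):
        sides[sign] = average_posterior(
            brain, exp, [sign * delta_s], [1.0], n_draws,
            np.random.default_rng(seeds[sign]), prior=prior,
        )
    delta = (sides[+1].mass - sides[-1].mass) / (2.0 * delta_s)
    return PosteriorDerivative(brain.grid, delta, wrt="s", step=delta_s)


def dposterior_dpi(
    brain: BrainModel,
    E: np.ndarray,
    priors: TaskPriors,
    delta_pi: float = 0.01,
    pi: float = 0.5,
    method: str = "fd",
) -> PosteriorDerivative:
    """Belief derivative of the posterior at a fixed observation.

    ``method="fd"`` is a central finite difference of `posterior_given_belief`
    over pi.  ``method="analytic"`` is the exact derivative of the normalized
    posterior (quotient rule).  ``method="analytic_simple"`` drops the
    normalization-derivative term, i.e. the likelihood-times-[p1 - p2] form
    that is exact when the zero-signal evidence is equally likely under both
    categories.
    """
    L = likelihood_values(brain, np.asarray(E, dtype=float).reshape(1, -1))[0]
    if method == "fd":
        if delta_pi <= 0:
            raise ValueError("delta_pi must be positive")
        if pi - delta_pi < 0 or pi + delta_pi > 1:
            raise ValueError("pi +/- delta_pi must stay inside [0, 1]")
        hi = posterior_given_belief(brain, E, pi + delta_pi, priors)
        lo = posterior_given_belief(brain, E, pi - delta_pi, priors)
        delta = (hi.mass - lo.mass) / (2.0 * delta_pi)
        return PosteriorDerivative(brain.grid, delta, wrt="pi", step=delta_pi)
    mix = pi * priors.p1.mass + (1.0 - pi) * priors.p2.mass
    diff = priors.p1.mass - priors.p2.mass
    z = (L * mix).sum()
    if z <= 0:
        raise ValueError("impossible evidence under the mixture prior")
    if method == "analytic":
        dz = (L * diff).sum()
        delta = (L * diff) / z - (L * mix) * dz / z**2
    elif method == "analytic_simple":
        # Mean-free only under category symmetry at s = 0; subtract the
        # residual mean so it remains a valid mass derivative.
        delta = (L * diff) / z
        delta = delta - delta.sum() / delta.size
    else:
        raise ValueError(f"unknown method {method!r}")
    return PosteriorDerivative(brain.grid, delta, wrt="pi", step=0.0)


def alignment(a: PosteriorDerivative, b: PosteriorDerivative) -> float:
    """Cosine similarity between two posterior-derivative fields."""
    if a.grid != b.grid:
        raise ValueError("derivatives live on different grids")
    return cosine_similarity(a.delta_mass, b.delta_mass)


def noise_averaged_dpi(
    brain: BrainModel,
    exp: ExperimenterModel,
    priors: TaskPriors,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    delta_pi: float = 0.01,
    method: str = "analytic",
) -> PosteriorDerivative:
    """Belief derivative averaged over zero-signal observation noise."""
    rng = np.random.default_rng(rng)
    deterministic = np.allclose(exp.cov(0.0), 0)
    draws = 1 if deterministic else n_draws
    E = sample_observation(exp, 0.0, rng, size=draws)
    acc = np.zeros(brain.grid.n_cells)
    for e in E:
        acc += dposterior_dpi(brain, e, priors, delta_pi=delta_pi, method=method).delta_mass
    step = delta_pi if method == "fd" else 0.0
    return PosteriorDerivative(brain.grid, acc / draws, wrt="pi", step=step)


def subthreshold_analysis(
    brain: BrainModel,
    exp: ExperimenterModel,
    n_draws: int = 500,
    rng: np.random.Generator | int = 0,
    n_fixed_point: int = 60,
    tol: float = 1e-10,
) -> dict:
    """Self-consistent observer and both posterior derivatives for one
    delta-mixture ensemble, all from a single likelihood-noise stream.

    One set of observation-noise draws is shared by the atom-wise average
    posteriors, the self-consistent prior (fixed-point iteration on cached
    likelihood rows), the category priors, dp/ds, and the noise-averaged
    dp/dpi.  Sharing the stream means the Monte-Carlo error of the +/-ds
    averages cancels in the comparison of the two derivative directions —
    without it the O(ds) signal would drown in sampling noise.
    """
    ens = exp.stimulus_dist
    if ens.kind != "delta_mixture":
        raise ValueError("sub-threshold analysis needs a delta-mixture ensemble")
    rng = np.random.default_rng(rng)
    ds, p0 = ens.delta_s, ens.p0
    atoms, _ = ens.atoms()  # (-ds, 0, +ds)
    deterministic = np.allclose(exp.cov(0.0), 0)
    draws = 1 if deterministic else n_draws
    z = rng.standard_normal((draws, 2))
    lik = {}
    for s_k in atoms:
        cov = exp.cov(s_k)
        root = np.linalg.cholesky(cov) if not np.allclose(cov, 0) else np.zeros((2, 2))
        E = exp.mean(s_k) + z @ root.T
        lik[s_k] = likelihood_values(brain, E)  # (draws, n_cells)

    def qbar(prior_mass: np.ndarray) -> dict:
        out = {}
        for s_k, L in lik.items():
            rows = _posterior_rows(prior_mass, L)
            out[s_k] = rows.mean(axis=0)
        return out

    # Fixed point of prior <- p0 q0 + (1 - p0)(q+ + q-)/2 on the shared draws.
    p = brain.prior.mass
    for _ in range(n_fixed_point):
        q = qbar(p)
        nxt = p0 * q[0.0] + (1 - p0) * 0.5 * (q[ds] + q[-ds])
        nxt /= nxt.sum()
        if 0.5 * np.abs(nxt - p).sum() < tol:
            p = nxt
            break
        p = nxt
    q = qbar(p)
    prior = ProbabilityField(brain.grid, p).normalize()
    p1 = ProbabilityField(brain.grid, (1 - p0) * q[ds] + p0 * q[0.0]).normalize()
    p2 = ProbabilityField(brain.grid, (1 - p0) * q[-ds] + p0 * q[0.0]).normalize()
    d_s = PosteriorDerivative(
        brain.grid, (q[ds] - q[-ds]) / (2 * ds), wrt="s", step=ds
    )
    # Noise-averaged analytic dp/dpi on the same zero-signal draws.
    L0 = lik[0.0]
    mix = 0.5 * (p1.mass + p2.mass)
    diff = p1.mass - p2.mass
    zmix = L0 @ mix
    zdiff = L0 @ diff
    rows = L0 * diff[None, :] / zmix[:, None] - (
        L0 * mix[None, :]
    ) * (zdiff / zmix**2)[:, None]
    d_pi = PosteriorDerivative(brain.grid, rows.mean(axis=0), wrt="pi", step=0.0)
    return dict(
        prior=prior,
        priors=TaskPriors(p1=p1, p2=p2),
        d_s=d_s,
        d_pi=d_pi,
        cosine=alignment(d_s, d_pi),
    )


def proportionality_experiment(
    brain: BrainModel,
    make_exp,
    delta_s_list,
    p0_list,
    n_draws: int = 500,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Cosine between dp/ds and dp/dpi across sub-threshold ensembles.

    ``make_exp(delta_s, p0)`` must return an `ExperimenterModel` with a
    delta-mixture stimulus ensemble.  For each (delta_s, p0) the observer's
    prior is set to its self-consistent fixed point before the derivatives
    are taken (see `subthreshold_analysis`).  The cosine approaches 1 as
    delta_s shrinks and p0 grows.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for ds in delta_s_list:
        for p0 in p0_list:
            exp = make_exp(ds, p0)
            sub = np.random.default_rng(int(rng.integers(2**31)))
            out = subthreshold_analysis(brain, exp, n_draws=n_draws, rng=sub)
            rows.append(dict(delta_s=ds, p0=p0, cosine=out["cosine"]))
    return pd.DataFrame(rows)


def category_decoder(
    brain: BrainModel, exp: ExperimenterModel, n_s: int = 201
) -> np.ndarray:
    """Implied decoder p_b(C=1|x) per grid cell.

    Quadrature over s of p_e(s) p_e(C=1|s) times the likelihood of the mean
    observation E(s) at each cell, normalized over the two categories.
    """
    ens = exp.stimulus_dist
    if ens.kind == "delta_mixture":
        s_nodes, w = ens.atoms()
    else:
        s_nodes = np.linspace(*ens.bounds, n_s)
        w = np.full(n_s, 1.0 / n_s)
    pc1 = np.where(s_nodes > 0, 1.0, np.where(s_nodes < 0, 0.0, ens.category_prior[0]))
    E_nodes = np.stack([experimenter_mean(exp, s) for s in s_nodes])
    L = likelihood_values(brain, E_nodes)  # (n_s, n_cells)
    num = (w[:, None] * pc1[:, None] * L).sum(axis=0)
    den = (w[:, None] * L).sum(axis=0)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), ens.category_prior[0])
    return np.clip(out, 0.0, 1.0)


def gaussian_mixture_demo(
    mu_x: float,
    sigma_x: float = 1.0,
    sigma_s: float = 1.0,
    grid: LatentGrid | None = None,
    delta_s: float = 0.01,
) -> dict:
    """1-D Gaussian-mixture observer: cosine between dp/ds and dp/dpi.

    The latent x is drawn from N(+mu_x, sigma_x^2) for category 1 and
    N(-mu_x, sigma_x^2) for category 2; the stimulus s is x plus Gaussian
    noise of SD sigma_s.  The posterior over x at s = 0 under the mixture
    prior is perturbed with respect to s (finite difference) and pi
    (analytic), and the cosine between the two derivative fields is
    returned.  The match improves as the categories approach (mu_x -> 0).
    """
    from scipy.stats import norm

    if grid is None:
        grid = LatentGrid(bounds=((-6.0, 6.0),), bins_per_dim=241)
    x = grid.cell_centers[:, 0]
    p1 = ProbabilityField(grid, norm.pdf(x, mu_x, sigma_x) * grid.cell_measure).normalize()
    p2 = ProbabilityField(grid, norm.pdf(x, -mu_x, sigma_x) * grid.cell_measure).normalize()
    mix = belief_prior(0.5, p1, p2)

    def post(s: float) -> np.ndarray:
        lik = norm.pdf(s, x, sigma_s)
        m = mix.mass * lik
        return m / m.sum()

    d_s = PosteriorDerivative(
        grid, (post(delta_s) - post(-delta_s)) / (2 * delta_s), wrt="s", step=delta_s
    )
    L0 = norm.pdf(0.0, x, sigma_s)
    z = (L0 * mix.mass).sum()
    dz = (L0 * (p1.mass - p2.mass)).sum()
    dpi = (L0 * (p1.mass - p2.mass)) / z - (L0 * mix.mass) * dz / z**2
    d_pi = PosteriorDerivative(grid, dpi, wrt="pi", step=0.0)
    return dict(cosine=alignment(d_s, d_pi), d_s=d_s, d_pi=d_pi, prior=mix)
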