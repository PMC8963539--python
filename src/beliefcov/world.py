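"""The experimenter's stimulus model and the brain's internal generative model.

The experimenter maps a scalar stimulus ``s`` to a 2-D observation ``E``
through a Gaussian p_e(E|s) whose mean or covariance carries the stimulus:

* ``mean_coded``       — mean (s, (s + s^3)/10), constant covariance 0.5 I.
* ``covariance_coded`` — zero mean; covariance S0 + tanh(s) S+ for s > 0 and
  S0 - tanh(s) S- for s <= 0, with S0 = 0.5 I and S+/- = [[1, +/-1], [+/-1, 1]].

The brain assumes E is generated from a latent x with an isotropic Gaussian
likelihood p_b(E|x) = N(E; x, sigma_e_sq I) and holds a prior p_b(x) on a
shared discretized grid; both E and x range over the same box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grid import LatentGrid, ProbabilityField
from .stimuli import StimulusEnsemble, uniform_ensemble

__all__ = [
    "ExperimenterModel",
    "BrainModel",
    "experimenter_mean",
    "experimenter_cov",
    "sample_observation",
    "sample_observations_batch",
    "likelihood_field",
    "likelihood_values",
    "evidence_marginal",
]

_S0 = 0.5 * np.eye(2)
_SPLUS = np.array([[1.0, 1.0], [1.0, 1.0]])
_SMINUS = np.array([[1.0, -1.0], [-1.0, 1.0]])


@dataclass(frozen=True)
class ExperimenterModel:
    """p_e(s) together with the observation family p_e(E|s).

    ``coding_mode`` selects between the two printed stimulus-observation
    mappings; ``custom`` accepts arbitrary ``mean_fn`` / ``cov_fn`` for
    controlled experiments (small-noise regimes, toy oracles).
    """

    stimulus_dist: StimulusEnsemble = field(default_factory=uniform_ensemble)
    coding_mode: str = "mean_coded"
    mean_fn: Callable[[float], np.ndarray] | None = None
    cov_fn: Callable[[float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.coding_mode not in ("mean_coded", "covariance_coded", "custom"):
            raise ValueError(f"unknown coding mode {self.coding_mode!r}")
        if self.coding_mode == "custom" and (self.mean_fn is None or self.cov_fn is None):
            raise ValueError("custom mode requires mean_fn and cov_fn")

    def mean(self, s: float) -> np.ndarray:
        return experimenter_mean(self, s)

    def cov(self, s: float) -> np.ndarray:
        return experimenter_cov(self, s)


def experimenter_mean(model: ExperimenterModel, s: float) -> np.ndarray:
    """Mean of p_e(E|s); (s, (s+s^3)/10) in the mean-coded task, else 0."""
    if not np.isfinite(s):
        raise ValueError("s must be finite")
    if model.coding_mode == "mean_coded":
        return np.array([s, (s + s**3) / 10.0])
    if model.coding_mode == "covariance_coded":
        return np.zeros(2)
    return np.asarray(model.mean_fn(s), dtype=float)


def experimenter_cov(model: ExperimenterModel, s: float) -> np.ndarray:
    """Covariance of p_e(E|s); branchwise-tanh family in the covariance task."""
    if not np.isfinite(s):
        raise ValueError("s must be finite")
    if model.coding_mode == "mean_coded":
        return _S0.copy()
    if model.coding_mode == "covariance_coded":
        if s > 0:
            return _S0 + np.tanh(s) * _SPLUS
        return _S0 - np.tanh(s) * _SMINUS
    return np.asarray(model.cov_fn(s), dtype=float)


def sample_observation(
    model: ExperimenterModel, s: float, rng: np.random.Generator | int, size: int | None = None
) -> np.ndarray:
    """Draw observation(s) E ~ p_e(E|s).

    Returns a 2-vector, or an ``(size, 2)`` array when ``size`` is given.
    """
    rng = np.random.default_rng(rng)
    mean, cov = experimenter_mean(model, s), experimenter_cov(model, s)
    if np.allclose(cov, 0):
        out = np.broadcast_to(mean, (size or 1, 2)).copy()
    else:
        out = rng.multivariate_normal(mean, cov, size=size or 1, method="cholesky")
    return out if size is not None else out[0]


def sample_observations_batch(
    model: ExperimenterModel, s: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Vectorized draws E_k ~ p_e(E|s_k) for an array of stimuli.

    Uses an analytic 2x2 Cholesky factor per draw; falls back to per-draw
    sampling for custom observation models.
    """
    rng = np.random.default_rng(rng)
    s = np.asarray(s, dtype=float)
    n = len(s)
    if model.coding_mode == "custom":
        return np.stack([sample_observation(model, s_k, rng) for s_k in s])
    if model.coding_mode == "mean_coded":
        mean = np.stack([s, (s + s**3) / 10.0], axis=1)
        a = np.full(n, 0.5)
        b = np.zeros(n)
        c = np.full(n, 0.5)
    else:
        mean = np.zeros((n, 2))
        t = np.tanh(s)
        # Both branches give diagonal 0.5 + |tanh s| and off-diagonal tanh s.
        a = 0.5 + np.abs(t)
        c = a
        b = t
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(np.maximum(c - l21**2, 0.0))
    z = rng.standard_normal((n, 2))
    return mean + np.stack([z[:, 0] * l11, z[:, 0] * l21 + z[:, 1] * l22], axis=1)


@dataclass
class BrainModel:
    """Internal generative model: isotropic Gaussian likelihood + grid prior.

    ``sigma_e_sq`` is the per-axis variance of p_b(E|x); the paper's two
    regimes are 0.04 (precise) and 0.36 (imprecise).
    """

    grid: LatentGrid
    sigma_e_sq: float = 0.36
    prior: ProbabilityField | None = None

    def __post_init__(self) -> None:
        if self.sigma_e_sq <= 0:
            raise ValueError("sigma_e_sq must be positive")
        if self.prior is None:
            self.prior = self.grid.uniform()
        elif self.prior.grid != self.grid or not self.prior.normalized:
            raise ValueError("prior must be a normalized field on the model grid")

    def with_prior(self, prior: ProbabilityField) -> "BrainModel":
        return BrainModel(self.grid, self.sigma_e_sq, prior.normalize())


def likelihood_values(brain: BrainModel, E: np.ndarray) -> np.ndarray:
    """Gaussian likelihood densities p_b(E|x_i) for a batch of observations.

    ``E`` has shape ``(n_draws, n_dims)``; the result has shape
    ``(n_draws, n_cells)``.  Not normalized over x.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    if not np.isfinite(E).all():
        raise ValueError("observations must be finite")
    centers = brain.grid.cell_centers  # (n_cells, d)
    d = brain.grid.n_dims
    sq = ((E[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    norm = (2.0 * np.pi * brain.sigma_e_sq) ** (d / 2.0)
    return np.exp(-0.5 * sq / brain.sigma_e_sq) / norm


def likelihood_field(brain: BrainModel, E: np.ndarray) -> ProbabilityField:
    """Likelihood of a single observation as an unnormalized field over x."""
    vals = likelihood_values(brain, np.asarray(E, dtype=float).reshape(1, -1))[0]
    return ProbabilityField(brain.grid, vals, normalized=False)


def evidence_marginal(
    model: ExperimenterModel, grid: LatentGrid, n_s: int = 301
) -> ProbabilityField:
    """Experimenter's marginal p_e(E) as a mass vector on the shared grid.

    Quadrature over s (trapezoid on the uniform ensemble's support, or the
    delta-mixture atoms), evaluating the Gaussian p_e(E|s) density at every
    cell center and renormalizing the truncated mass on the grid.
    """
    ens = model.stimulus_dist
    if ens.kind == "uniform":
        s_nodes = np.linspace(*ens.bounds, n_s)
        w = np.full(n_s, 1.0 / n_s)
    else:
        s_nodes, w = ens.atoms()
    centers = grid.cell_centers
    dens = np.zeros(grid.n_cells)
    for s_k, w_k in zip(s_nodes, w):
        if w_k == 0:
            continue
        mean, cov = experimenter_mean(model, s_k), experimenter_cov(model, s_k)
        diff = centers - mean
        prec = np.linalg.inv(cov)
        quad = np.einsum("nd,de,ne->n", diff, prec, diff)
        norm = (2 * np.pi) ** (grid.n_dims / 2) * np.sqrt(np.linalg.det(cov))
        dens += w_k * np.exp(-0.5 * quad) / norm
    mass = dens * grid.cell_measure
    return ProbabilityField(grid, mass).normalize()
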