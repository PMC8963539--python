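"""Distributional codes: mapping posterior fields to spike counts.

A distributional code R sends a probability field over the latent grid to a
distribution over neural responses; tuning curves are the expected counts as
a function of the stimulus.  Four concrete kinds are provided:

* ``linear_sampling`` — k latent samples drawn from the field are binned by
  each neuron's preferred (Voronoi) region; expected counts are linear in
  the encoded mass, so this is a Linear Distributional Code (LDC).
* ``linear_moment``   — rates are a fixed linear readout of the mass vector
  (Gaussian-bump weights over cells); also an LDC.
* ``nonlinear_rate``  — a squared linear readout; convexity produces a
  Jensen gap for mixtures, so the LDC property fails.
* ``natural_param``   — rates read out the floored log-mass, a minimal
  exponential-family-parameter encoding; also non-LDC.

All kinds emit Poisson spike counts around their (possibly stochastic)
per-trial rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LatentGrid, ProbabilityField
from .inference import TaskPriors
from .world import BrainModel, ExperimenterModel, likelihood_values, sample_observation

__all__ = [
    "DistributionalCode",
    "make_code",
    "mean_rates",
    "mean_rates_batch",
    "sample_response",
    "sample_responses",
    "ldc_mixture_gap",
    "TuningCurve",
    "tuning_curve",
]

_KINDS = ("linear_sampling", "linear_moment", "nonlinear_rate", "natural_param")
_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class DistributionalCode:
    """Readout weights plus the encoding nonlinearity kind."""

    kind: str
    weights: np.ndarray  # (n_neurons, n_cells), nonnegative
    gain: float = 10.0
    baseline: float = 0.0  # stimulus-independent rate offset (spikes/trial)
    k_samples: int = 20  # latent samples per trial (sampling kind only)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown code kind {self.kind!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or np.any(w < 0):
            raise ValueError("weights must be a nonnegative 2-D array")
        object.__setattr__(self, "weights", w)
        if self.gain < 0 or self.k_samples < 1 or self.baseline < 0:
            raise ValueError("gain, baseline and k_samples must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def is_linear(self) -> bool:
        return self.kind in ("linear_sampling", "linear_moment")


def make_code(
    kind: str,
    grid: LatentGrid,
    n_neurons: int,
    gain: float = 10.0,
    baseline: float = 0.0,
    bump_width: float = 1.0,
    k_samples: int = 20,
    rng: np.random.Generator | int = 0,
) -> DistributionalCode:
    """Build a code with preferred points spread evenly over the grid.

    ``linear_sampling`` uses 0/1 Voronoi membership of cells to preferred
    points; the other kinds use normalized Gaussian-bump weights of width
    ``bump_width`` (latent units) around each preferred point.
    """
    rng = np.random.default_rng(rng)
    centers = grid.cell_centers
    # Evenly spaced preferred points with a small jitter to break ties.
    idx = np.linspace(0, grid.n_cells - 1, n_neurons).round().astype(int)
    preferred = centers[idx] + rng.normal(0, 1e-6, size=(n_neurons, grid.n_dims))
    d2 = ((preferred[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    if kind == "linear_sampling":
        owner = np.argmin(d2, axis=0)  # nearest preferred point per cell
        weights = np.zeros((n_neurons, grid.n_cells))
        weights[owner, np.arange(grid.n_cells)] = 1.0
    else:
        weights = np.exp(-0.5 * d2 / bump_width**2)
        weights /= weights.sum(axis=1, keepdims=True)
    return DistributionalCode(
        kind=kind, weights=weights, gain=gain, baseline=baseline, k_samples=k_samples
    )


def mean_rates(code: DistributionalCode, field: ProbabilityField) -> np.ndarray:
    """Expected spike count per neuron for one encoded field; deterministic."""
    return mean_rates_batch(code, field.mass[None, :])[0]


def mean_rates_batch(code: DistributionalCode, mass_rows: np.ndarray) -> np.ndarray:
    """Expected counts for a batch of mass vectors, shape (n_rows, n_neurons)."""
    mass_rows = np.atleast_2d(mass_rows)
    if code.kind == "natural_param":
        feat = np.log(np.maximum(mass_rows, _LOG_FLOOR) / _LOG_FLOOR)
        return code.baseline + code.gain * feat @ code.weights.T
    lin = code.gain * mass_rows @ code.weights.T
    if code.kind == "nonlinear_rate":
        return code.baseline + lin**2 / code.gain  # squared readout, gain units
    return code.baseline + lin


def _sampling_rate_hat(
    code: DistributionalCode, mass_rows: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-trial empirical rates of the sampling code (k samples, binned)."""
    n_rows, n_cells = mass_rows.shape
    cdf = np.cumsum(mass_rows, axis=1)
    cdf /= cdf[:, -1:]
    owner = np.argmax(code.weights > 0, axis=0)  # cell -> neuron (0/1 weights)
    rates = np.empty((n_rows, code.n_neurons))
    u = rng.random((n_rows, code.k_samples))
    for r in range(n_rows):
        cells = np.searchsorted(cdf[r], u[r], side="right")
        counts = np.bincount(owner[cells], minlength=code.n_neurons)
        rates[r] = code.gain * counts / code.k_samples
    return rates


def sample_responses(
    code: DistributionalCode,
    mass_rows: np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Poisson spike counts for a batch of encoded fields."""
    rng = np.random.default_rng(rng)
    mass_rows = np.atleast_2d(mass_rows)
    if code.kind == "linear_sampling":
        lam = code.baseline + _sampling_rate_hat(code, mass_rows, rng)
    else:
        lam = mean_rates_batch(code, mass_rows)
    return rng.poisson(np.maximum(lam, 0.0))


def sample_response(
    code: DistributionalCode, field: ProbabilityField, rng: np.random.Generator | int
) -> np.ndarray:
    """One spike-count vector for one encoded field."""
    return sample_responses(code, field.mass[None, :], rng)[0]


def ldc_mixture_gap(
    code: DistributionalCode,
    p1: ProbabilityField,
    p2: ProbabilityField,
    alpha: float,
    n_mc: int = 0,
    rng: np.random.Generator | int = 0,
) -> dict:
    """Mixture-linearity gap |E S(alpha p1 + (1-alpha) p2) - mixture of E S|.

    With ``n_mc`` = 0 the gap is computed exactly from `mean_rates`
    (identically zero for linear kinds); with ``n_mc`` > 0 it is estimated
    from sampled responses, and the per-neuron Monte-Carlo standard error of
    the gap is returned alongside.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    mix = ProbabilityField(
        p1.grid, alpha * p1.mass + (1 - alpha) * p2.mass, normalized=True
    )
    if n_mc == 0:
        gap = mean_rates(code, mix) - (
            alpha * mean_rates(code, p1) + (1 - alpha) * mean_rates(code, p2)
        )
        return dict(gap=np.abs(gap), se=np.zeros(code.n_neurons))
    rng = np.random.default_rng(rng)
    resp = {
        name: sample_responses(code, np.tile(f.mass, (n_mc, 1)), rng)
        for name, f in (("mix", mix), ("p1", p1), ("p2", p2))
    }
    gap = resp["mix"].mean(0) - (alpha * resp["p1"].mean(0) + (1 - alpha) * resp["p2"].mean(0))
    var = (
        resp["mix"].var(0, ddof=1)
        + alpha**2 * resp["p1"].var(0, ddof=1)
        + (1 - alpha) ** 2 * resp["p2"].var(0, ddof=1)
    ) / n_mc
    return dict(gap=np.abs(gap), se=np.sqrt(var))


@dataclass
class TuningCurve:
    """Noise-averaged rates f_i(s), slope f' at s = 0, and response SD there."""

    s_values: np.ndarray
    rates: np.ndarray  # (n_neurons, n_s)
    fprime: np.ndarray
    sigma: np.ndarray

    def dprime(self) -> np.ndarray:
        if np.any(self.sigma <= 0):
            raise ValueError("zero response SD; d-prime undefined")
        return self.fprime / self.sigma


def tuning_curve(
    code: DistributionalCode,
    brain: BrainModel,
    exp: ExperimenterModel,
    s_values: np.ndarray,
    priors: TaskPriors | None = None,
    pi: float = 0.5,
    n_draws: int = 500,
    delta_s: float = 0.01,
    rng: np.random.Generator | int = 0,
) -> TuningCurve:
    """Tuning curves f_i(s) = E_noise[ mean_rates(posterior at s) ].

    The slope f' is a central finite difference of noise-averaged rates at
    s = +/-delta_s; sigma is the SD of sampled spike counts at s = 0.
    """
    s_values = np.asarray(s_values, dtype=float)
    if np.any(np.diff(s_values) <= 0):
        raise ValueError("s_values must be strictly increasing")
    rng = np.random.default_rng(rng)
    prior = priors.marginal(pi) if priors is not None else brain.prior
    # One observation-noise stream shared across all stimulus values
    # (common random numbers), so the f' finite difference is not drowned
    # by independent Monte-Carlo noise on the two sides.
    noise_seed = int(rng.integers(2**31))

    def avg_rates(s: float) -> np.ndarray:
        deterministic = np.allclose(exp.cov(s), 0)
        draws = 1 if deterministic else n_draws
        E = sample_observation(exp, s, np.random.default_rng(noise_seed), size=draws)
        L = likelihood_values(brain, E)
        post = L * prior.mass[None, :]
        post /= post.sum(axis=1, keepdims=True)
        return mean_rates_batch(code, post).mean(axis=0), post

    rates = np.stack([avg_rates(s)[0] for s in s_values], axis=1)
    f_plus, _ = avg_rates(delta_s)
    f_minus, _ = avg_rates(-delta_s)
    fprime = (f_plus - f_minus) / (2 * delta_s)
    _, post0 = avg_rates(0.0)
    if post0.shape[0] == 1:  # deterministic observations: replicate trials
        post0 = np.tile(post0, (n_draws, 1))
    responses = sample_responses(code, post0, rng)
    sigma = responses.std(axis=0, ddof=1)
    return TuningCurve(s_values=s_values, rates=rates, fprime=fprime, sigma=sigma)
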