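"""Stimulus ensembles and belief streams.

The experimenter controls a scalar stimulus ``s`` with category boundary at
``s = 0``.  Two ensembles are supported:

* ``uniform`` — s ~ U(lo, hi), the training ensemble used for prior learning
  (default bounds [-3, 3]); the category is the sign of s.
* ``delta_mixture`` — the sub-threshold 2AFC ensemble: s takes the values
  {-ds, 0, +ds} with probabilities ((1-p0)/2, p0, (1-p0)/2).  Zero-signal
  stimuli occur with probability p0 so that derivatives at s = 0 are
  well-defined in practice.

Category convention: category 1 is associated with s > 0 (s = +ds in the
delta mixture), category 2 with s < 0.  Zero-signal stimuli are assigned a
category uniformly at random.

Beliefs pi (the observer's probability that the category is 1) are drawn
i.i.d. from a symmetric Beta(a, a) distribution on [0, 1]; ``a`` is set from
the requested variance through var = 1 / (4 (2a + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusEnsemble",
    "uniform_ensemble",
    "delta_mixture_ensemble",
    "sample_stimuli",
    "sample_beliefs",
    "beta_shape_from_variance",
    "make_fixture",
]


@dataclass(frozen=True)
class StimulusEnsemble:
    """Distribution p_e(s) together with the category structure p_e(s|C)."""

    kind: str  # "uniform" | "delta_mixture"
    bounds: tuple[float, float] = (-3.0, 3.0)
    p0: float = 0.5
    delta_s: float = 0.1
    category_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "delta_mixture"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")
        if not np.isfinite(self.bounds).all():
            raise ValueError("uniform bounds must be finite")
        if abs(sum(self.category_prior) - 1.0) > 1e-12:
            raise ValueError("category prior must sum to 1")

    def atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """Support points and probabilities of p_e(s) (delta mixture only)."""
        if self.kind != "delta_mixture":
            raise ValueError("atoms are defined only for the delta mixture")
        s = np.array([-self.delta_s, 0.0, self.delta_s])
        w = np.array([(1 - self.p0) / 2, self.p0, (1 - self.p0) / 2])
        return s, w

    def category_atoms(self, c: int) -> tuple[np.ndarray, np.ndarray]:
        """Support and probabilities of p_e(s|C=c); category 1 <-> s > 0."""
        if self.kind != "delta_mixture":
            raise ValueError("category atoms are defined only for the delta mixture")
        if c not in (1, 2):
            raise ValueError("category must be 1 or 2")
        signed = self.delta_s if c == 1 else -self.delta_s
        return np.array([signed, 0.0]), np.array([1 - self.p0, self.p0])


def uniform_ensemble(lo: float = -3.0, hi: float = 3.0) -> StimulusEnsemble:
    return StimulusEnsemble(kind="uniform", bounds=(lo, hi))


def delta_mixture_ensemble(p0: float, delta_s: float) -> StimulusEnsemble:
    return StimulusEnsemble(kind="delta_mixture", p0=p0, delta_s=delta_s)


def sample_stimuli(
    ensemble: StimulusEnsemble, n: int, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (s, C) pairs; returns arrays of stimuli and categories."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    if ensemble.kind == "uniform":
        s = rng.uniform(*ensemble.bounds, size=n)
    else:
        atoms, probs = ensemble.atoms()
        s = atoms[rng.choice(3, size=n, p=probs)]
    c = np.where(s > 0, 1, np.where(s < 0, 2, 0))
    zero = c == 0
    c[zero] = rng.choice([1, 2], size=zero.sum(), p=ensemble.category_prior)
    return s, c


def beta_shape_from_variance(var_pi: float) -> float:
    """Shape ``a`` of the symmetric Beta(a, a) with the given variance.

    var = 1 / (4 (2a + 1)); var -> 0.25 corresponds to a -> 0 (fair coin on
    {0, 1}) and var -> 0 to a point mass at 1/2.
    """
    if not 0.0 <= var_pi <= 0.25:
        raise ValueError("var_pi must lie in [0, 0.25] for support on [0, 1]")
    if var_pi == 0.25:
        return 0.0
    return (1.0 / (4.0 * var_pi) - 1.0) / 2.0


def sample_beliefs(
    var_pi: float, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """i.i.d. symmetric beliefs on [0, 1] with mean 1/2 and variance var_pi."""
    rng = np.random.default_rng(rng)
    if var_pi == 0.0:
        return np.full(n, 0.5)
    a = beta_shape_from_variance(var_pi)
    if a == 0.0:
        return rng.choice([0.0, 1.0], size=n)
    return rng.beta(a, a, size=n)


def make_fixture(profile: str) -> dict:
    """Named experiment configurations.

    ``tiny``  — 21-bin grids and reduced draw counts, for fast test suites.
    ``small`` — 41-bin grids with the full training schedule, a scaled-down
                version of the printed configuration.
    ``paper`` — the printed configuration: 85 bins per dimension on [-5, 5]^2,
                1000 likelihood draws per learning iteration, 2000 draws for
                posterior-covariance estimation.
    """
    profiles = {
        "tiny": dict(bins_per_dim=21, draws_per_iteration=200, n_iterations=60,
                     sigma_draws=400, n_repeats=2),
        "small": dict(bins_per_dim=41, draws_per_iteration=1000, n_iterations=300,
                      sigma_draws=2000, n_repeats=4),
        "paper": dict(bins_per_dim=85, draws_per_iteration=1000, n_iterations=300,
                      sigma_draws=2000, n_repeats=4),
    }
    if profile not in profiles:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(profiles)}")
    cfg = dict(profiles[profile])
    cfg.update(
        profile=profile,
        bounds=((-5.0, 5.0), (-5.0, 5.0)),
        stimulus_bounds=(-3.0, 3.0),
        sigma_e_sq=dict(precise=0.04, imprecise=0.36),
        lambda_entropy=1e-3,
        initial_step=100.0,
        halving_period=100,
        delta_s=0.01,
    )
    return cfg
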