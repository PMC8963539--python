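"""Discretized latent spaces and probability-mass vectors.

All inference in this package happens on a regular grid over a 1-D or 2-D
latent space.  Distributions are represented as finite vectors of probability
*mass* per grid cell (density x cell measure), which makes normalization exact
and keeps entropy/KL computations explicit about grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatentGrid",
    "ProbabilityField",
    "cosine_similarity",
    "total_variation",
]

_NORM_TOL = 1e-10


@dataclass(frozen=True)
class LatentGrid:
    """Regular discretization of a closed box in 1-D or 2-D latent space.

    Parameters
    ----------
    bounds :
        Per-dimension ``(lo, hi)`` intervals, e.g. ``((-5, 5), (-5, 5))``.
    bins_per_dim :
        Number of cells along each dimension (shared across dimensions).
    """

    bounds: tuple[tuple[float, float], ...]
    bins_per_dim: int

    def __post_init__(self) -> None:
        if self.bins_per_dim < 1:
            raise ValueError("bins_per_dim must be >= 1")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(bounds) not in (1, 2):
            raise ValueError("only 1-D and 2-D grids are supported")
        for lo, hi in bounds:
            if not np.isfinite([lo, hi]).all() or hi <= lo:
                raise ValueError(f"invalid interval ({lo}, {hi})")
        object.__setattr__(self, "bounds", bounds)

    @property
    def n_dims(self) -> int:
        return len(self.bounds)

    @property
    def n_cells(self) -> int:
        return self.bins_per_dim ** self.n_dims

    @property
    def cell_widths(self) -> np.ndarray:
        return np.array([(hi - lo) / self.bins_per_dim for lo, hi in self.bounds])

    @property
    def cell_measure(self) -> float:
        """Length (1-D) or area (2-D) of a single cell."""
        return float(np.prod(self.cell_widths))

    def axis_centers(self, dim: int) -> np.ndarray:
        lo, hi = self.bounds[dim]
        w = (hi - lo) / self.bins_per_dim
        return lo + w * (np.arange(self.bins_per_dim) + 0.5)

    @property
    def cell_centers(self) -> np.ndarray:
        """``(n_cells, n_dims)`` array of cell-center coordinates.

        2-D cells are ordered with the first axis varying slowest
        (C order over ``(axis0, axis1)``).
        """
        axes = [self.axis_centers(d) for d in range(self.n_dims)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def uniform(self) -> "ProbabilityField":
        return ProbabilityField(
            self, np.full(self.n_cells, 1.0 / self.n_cells), normalized=True
        )


@dataclass
class ProbabilityField:
    """Nonnegative mass vector on a :class:`LatentGrid`.

    ``normalized=True`` asserts the masses sum to one (posteriors, priors);
    unnormalized fields hold likelihood values p_b(E|x) per cell.
    """

    grid: LatentGrid
    mass: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.grid.n_cells,):
            raise ValueError(
                f"mass has shape {self.mass.shape}, expected ({self.grid.n_cells},)"
            )
        if np.any(self.mass < 0):
            raise ValueError("mass entries must be nonnegative")
        if self.normalized and abs(self.mass.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"mass sums to {self.mass.sum():.3e}, not 1")

    def normalize(self) -> "ProbabilityField":
        total = self.mass.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero field")
        return ProbabilityField(self.grid, self.mass / total, normalized=True)

    @property
    def density(self) -> np.ndarray:
        """Probability density per cell (mass / cell measure)."""
        return self.mass / self.grid.cell_measure

    def entropy(self) -> float:
        """Shannon entropy of the mass vector, -sum m log m (nats).

        Uses the mass convention: a uniform field on n cells has entropy log n.
        """
        m = self.mass[self.mass > 0]
        return float(-(m * np.log(m)).sum())

    def as_array(self) -> np.ndarray:
        """Mass reshaped to the grid (``bins_per_dim`` per axis)."""
        shape = (self.grid.bins_per_dim,) * self.grid.n_dims
        return self.mass.reshape(shape)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def total_variation(p: ProbabilityField, q: ProbabilityField) -> float:
    """Total-variation distance between two normalized fields on one grid."""
    if p.grid != q.grid:
        raise ValueError("fields live on different grids")
    return float(0.5 * np.abs(p.mass - q.mass).sum())
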