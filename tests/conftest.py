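import numpy as np
import pytest

from beliefcov import (
    BrainModel,
    ExperimenterModel,
    LatentGrid,
    ProbabilityField,
    delta_mixture_ensemble,
    uniform_ensemble,
)


@pytest.fixture(scope="session")
def grid21():
    return LatentGrid(bounds=((-5.0, 5.0), (-5.0, 5.0)), bins_per_dim=21)


@pytest.fixture(scope="session")
def grid1d():
    return LatentGrid(bounds=((-6.0, 6.0),), bins_per_dim=121)


@pytest.fixture(scope="session")
def grid3():
    """Three-cell 1-D grid for hand-computed Bayes examples."""
    return LatentGrid(bounds=((0.0, 3.0),), bins_per_dim=3)


@pytest.fixture
def mean_exp():
    return ExperimenterModel(stimulus_dist=uniform_ensemble(), coding_mode="mean_coded")


@pytest.fixture
def cov_exp():
    return ExperimenterModel(
        stimulus_dist=uniform_ensemble(), coding_mode="covariance_coded"
    )


@pytest.fixture
def imprecise_brain(grid21):
    return BrainModel(grid21, sigma_e_sq=0.36)


@pytest.fixture
def precise_brain(grid21):
    return BrainModel(grid21, sigma_e_sq=0.04)


def zero_noise_exp(ensemble=None, mean_fn=None):
    """Deterministic observation model (cov = 0) on the cubic stimulus axis."""
    zero = np.zeros((2, 2))
    return ExperimenterModel(
        stimulus_dist=ensemble or delta_mixture_ensemble(0.5, 0.5),
        coding_mode="custom",
        mean_fn=mean_fn or (lambda s: np.array([s, (s + s**3) / 10.0])),
        cov_fn=lambda s: zero,
    )


@pytest.fixture
def field3(grid3):
    return ProbabilityField(grid3, np.array([0.2, 0.3, 0.5]), normalized=True)
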