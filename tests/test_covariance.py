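import numpy as np
import pytest
from scipy.stats import norm

from beliefcov import (
    BrainModel,
    DensityCovariance,
    ExperimenterModel,
    LatentGrid,
    LearningSchedule,
    ProbabilityField,
    delta_mixture_ensemble,
    empirical_sigma_lh,
    empirical_sigma_p,
    filter_experiment,
    filtered_sigma,
    fraction_along,
    fraction_along_draws,
    likelihood_values,
    posterior_draws,
    uniform_ensemble,
)
from beliefcov.covariance import LikelihoodCovariance
from beliefcov.world import sample_observation

from conftest import zero_noise_exp


def _small_noise_exp(tau):
    return ExperimenterModel(
        stimulus_dist=uniform_ensemble(),
        coding_mode="custom",
        mean_fn=lambda s: np.array([s, 0.0]),
        cov_fn=lambda s: tau**2 * np.eye(2),
    )


class TestEmpiricalCovariances:
    def test_zero_observation_noise_gives_zero_covariance(self, imprecise_brain):
        exp = zero_noise_exp()
        sp = empirical_sigma_p(imprecise_brain, exp, n_draws=20, rng=0)
        sl = empirical_sigma_lh(imprecise_brain, exp, n_draws=20, rng=0)
        assert np.abs(sp.matrix).max() == pytest.approx(0.0, abs=1e-18)
        assert np.abs(sl.matrix).max() == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_psd(self, imprecise_brain, mean_exp):
        sp = empirical_sigma_p(imprecise_brain, mean_exp, n_draws=60, rng=1)
        assert np.allclose(sp.matrix, sp.matrix.T)
        eig = np.linalg.eigvalsh(sp.matrix)
        assert eig.min() > -1e-8 * max(np.trace(sp.matrix), 1e-30)

    def test_likelihood_covariance_matches_two_pass_oracle(self, imprecise_brain, mean_exp):
        E = sample_observation(mean_exp, 0.0, np.random.default_rng(2), size=50)
        sl = empirical_sigma_lh(imprecise_brain, mean_exp, E=E)
        L = likelihood_values(imprecise_brain, E)
        mu = L.mean(axis=0)
        oracle = (L - mu).T @ (L - mu) / (len(E) - 1)
        assert np.allclose(sl.matrix, oracle, atol=1e-12)

    def test_1d_small_noise_top_eigenvector_is_translation_mode(self):
        """Small observation jitter of a 1-D Gaussian posterior varies the
        density along its translation derivative."""
        grid = LatentGrid(bounds=((-6.0, 6.0),), bins_per_dim=151)
        brain = BrainModel(grid, sigma_e_sq=1.0)
        exp = ExperimenterModel(
            coding_mode="custom",
            mean_fn=lambda s: np.array([s]),
            cov_fn=lambda s: np.array([[0.01]]),
        )
        sp = empirical_sigma_p(brain, exp, n_draws=400, rng=3)
        top = sp.top_eigenvector()
        x = grid.cell_centers[:, 0]
        dpds = (x / 1.0) * norm.pdf(x, 0, 1.0)  # d/dmu of N(mu=0, 1)
        cos = abs(top @ dpds) / np.linalg.norm(dpds)
        assert cos > 0.99


class TestFilteredSigma:
    def test_uniform_prior_rescales_likelihood_covariance(self, grid21, imprecise_brain, mean_exp):
        sl = empirical_sigma_lh(imprecise_brain, mean_exp, n_draws=40, rng=0)
        filt = filtered_sigma(grid21.uniform(), sl)
        scale = (1.0 / grid21.n_cells) ** 2
        assert np.allclose(filt.matrix, scale * sl.matrix)

    def test_zero_prior_cell_annihilates_row_and_column(self, grid3):
        prior = ProbabilityField(grid3, np.array([0.5, 0.0, 0.5]), normalized=True)
        sl = LikelihoodCovariance(grid3, np.full((3, 3), 2.0), n_draws=10)
        filt = filtered_sigma(prior, sl)
        assert np.all(filt.matrix[1, :] == 0) and np.all(filt.matrix[:, 1] == 0)

    def test_top_eigenspace_matches_empirical_in_small_noise_regime(self, grid21):
        """First-order check of the prior-filtering factorization: principal
        angle between the top eigenvectors below 10 degrees."""
        brain = BrainModel(grid21, sigma_e_sq=0.36)
        exp = _small_noise_exp(tau=0.1)
        # a structured, smooth prior (Gaussian ridge along the axis)
        c = grid21.cell_centers
        mass = np.exp(-0.5 * (c[:, 0] ** 2 / 4.0 + c[:, 1] ** 2 / 0.8))
        prior = ProbabilityField(grid21, mass / mass.sum(), normalized=True)
        brain = brain.with_prior(prior)
        E = sample_observation(exp, 0.0, np.random.default_rng(5), size=1500)
        sp = empirical_sigma_p(brain, exp, E=E)
        sl = empirical_sigma_lh(brain, exp, E=E)
        filt = filtered_sigma(prior, sl)
        v1 = sp.top_eigenvector()
        v2 = filt.top_eigenvector()
        angle = np.degrees(np.arccos(min(abs(v1 @ v2), 1.0)))
        assert angle < 10.0


class TestFractionAlong:
    def test_isotropic_covariance_gives_one_over_d(self, grid3):
        cov = DensityCovariance(grid3, np.eye(3), n_draws=10)
        u = np.array([1.0, 0.0, 0.0])
        assert fraction_along(u, cov) == pytest.approx(1 / 3)

    def test_aligned_rank_one_gives_one(self, grid3):
        u = np.array([1.0, 2.0, -1.0])
        u /= np.linalg.norm(u)
        cov = DensityCovariance(grid3, np.outer(u, u), n_draws=10)
        assert fraction_along(u, cov) == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle_and_scale_invariance(self, grid3):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        M = A @ A.T
        cov = DensityCovariance(grid3, M, n_draws=10)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        vals, vecs = np.linalg.eigh(M)
        oracle = ((vecs.T @ u) ** 2 * vals).sum() / vals.sum()
        assert fraction_along(u, cov) == pytest.approx(oracle, rel=1e-12)
        scaled = DensityCovariance(grid3, 17.3 * M, n_draws=10)
        assert fraction_along(u, scaled) == pytest.approx(fraction_along(u, cov))

    def test_streaming_equals_dense(self, imprecise_brain, mean_exp):
        rows = posterior_draws(imprecise_brain, mean_exp, n_draws=80, rng=1)
        cov = DensityCovariance(
            imprecise_brain.grid, np.cov(rows, rowvar=False), n_draws=80
        )
        u = rows[0] - rows[1]
        u /= np.linalg.norm(u)
        assert fraction_along_draws(u, rows) == pytest.approx(
            fraction_along(u, cov), rel=1e-10
        )

    def test_zero_trace_errors(self, grid3):
        cov = DensityCovariance(grid3, np.zeros((3, 3)), n_draws=10)
        with pytest.raises(ValueError):
            fraction_along(np.array([1.0, 0, 0]), cov)


class TestFilterExperiment:
    def test_fixed_seed_reproduces_tables(self):
        grid = LatentGrid(bounds=((-5.0, 5.0),) * 2, bins_per_dim=15)
        exp = ExperimenterModel(stimulus_dist=uniform_ensemble(), coding_mode="mean_coded")
        sched = LearningSchedule(n_iterations=15, draws_per_iteration=100)
        kw = dict(
            schedule=sched, n_repeats=2, sigma_draws=200, dpds_draws=100, seed=3
        )
        a = filter_experiment("mean_coded", "imprecise", exp, grid, **kw)
        b = filter_experiment("mean_coded", "imprecise", exp, grid, **kw)
        assert a.equals(b)
        assert set(a.columns) >= {"fraction_before", "fraction_after", "repeat"}
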