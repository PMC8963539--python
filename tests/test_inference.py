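import numpy as np
import pytest
from scipy.stats import norm

from beliefcov import (
    BrainModel,
    LatentGrid,
    ProbabilityField,
    TaskPriors,
    alignment,
    belief_prior,
    category_decoder,
    category_prior,
    delta_mixture_ensemble,
    dposterior_dpi,
    dposterior_ds,
    gaussian_mixture_demo,
    likelihood_field,
    posterior,
    posterior_given_belief,
)
from beliefcov.inference import PosteriorDerivative, subthreshold_analysis

from conftest import zero_noise_exp


class TestPosterior:
    def test_flat_prior_returns_normalized_likelihood(self, grid3):
        prior = grid3.uniform()
        lik = ProbabilityField(grid3, np.array([1.0, 2.0, 1.0]))
        post = posterior(prior, lik)
        assert np.allclose(post.mass, [0.25, 0.5, 0.25])

    def test_point_mass_prior_is_fixed(self, grid3):
        prior = ProbabilityField(grid3, np.array([0.0, 1.0, 0.0]), normalized=True)
        lik = ProbabilityField(grid3, np.array([5.0, 0.1, 3.0]))
        assert np.allclose(posterior(prior, lik).mass, [0, 1, 0])

    def test_hand_computed_bayes(self, grid3, field3):
        lik = ProbabilityField(grid3, np.array([1.0, 2.0, 1.0]))
        post = posterior(field3, lik)
        assert np.allclose(post.mass, np.array([0.2, 0.6, 0.5]) / 1.3)

    def test_impossible_evidence_errors(self, grid3):
        prior = ProbabilityField(grid3, np.array([1.0, 0.0, 0.0]), normalized=True)
        lik = ProbabilityField(grid3, np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            posterior(prior, lik)


class TestBeliefPrior:
    def test_affine_mixture(self, grid3):
        p1 = ProbabilityField(grid3, np.array([1.0, 0.0, 0.0]), normalized=True)
        p2 = ProbabilityField(grid3, np.array([0.0, 0.0, 1.0]), normalized=True)
        assert np.allclose(belief_prior(1.0, p1, p2).mass, p1.mass)
        assert np.allclose(belief_prior(0.5, p1, p2).mass, [0.5, 0, 0.5])
        assert np.allclose(belief_prior(0.25, p1, p2).mass, [0.25, 0, 0.75])
        with pytest.raises(ValueError):
            belief_prior(1.2, p1, p2)

    def test_identical_category_priors_make_belief_irrelevant(self, grid3, field3):
        brain = BrainModel(grid3, sigma_e_sq=0.5)
        priors = TaskPriors(p1=field3, p2=field3)
        a = posterior_given_belief(brain, [1.2], 0.1, priors)
        b = posterior_given_belief(brain, [1.2], 0.9, priors)
        assert np.allclose(a.mass, b.mass)

    def test_matches_enumerated_joint_oracle(self, grid3):
        """Explicit sum over (C, x) cells reproduces the mixture posterior."""
        brain = BrainModel(grid3, sigma_e_sq=0.3)
        p1 = ProbabilityField(grid3, np.array([0.6, 0.3, 0.1]), normalized=True)
        p2 = ProbabilityField(grid3, np.array([0.1, 0.2, 0.7]), normalized=True)
        E, pi = np.array([1.7]), 0.3
        result = posterior_given_belief(brain, E, pi, TaskPriors(p1=p1, p2=p2))
        lik = likelihood_field(brain, E).mass
        joint = np.zeros(3)
        for w, p in ((pi, p1.mass), (1 - pi, p2.mass)):
            for i in range(3):
                joint[i] += w * p[i] * lik[i]
        assert np.allclose(result.mass, joint / joint.sum())


class TestDerivatives:
    def test_stimulus_derivative_is_mean_free(self, imprecise_brain, mean_exp):
        d = dposterior_ds(imprecise_brain, mean_exp, n_draws=50, rng=0)
        assert abs(d.delta_mass.sum()) < 1e-8

    def test_matches_analytic_gaussian_shift(self):
        """Zero-noise 1-D observer: finite difference vs the closed-form
        derivative of a translated Gaussian posterior."""
        grid = LatentGrid(bounds=((-6.0, 6.0),), bins_per_dim=301)
        x = grid.cell_centers[:, 0]
        sig_p, sig_l = 1.5, 0.8
        prior = ProbabilityField(grid, norm.pdf(x, 0, sig_p) * grid.cell_measure).normalize()
        w = sig_p**2 / (sig_p**2 + sig_l**2)  # posterior-mean gain d mu / ds
        sig_post = np.sqrt(sig_p**2 * sig_l**2 / (sig_p**2 + sig_l**2))

        def post_mass(s):
            m = prior.mass * norm.pdf(s, x, sig_l)
            return m / m.sum()

        delta = 1e-3
        fd = (post_mass(delta) - post_mass(-delta)) / (2 * delta)
        analytic = w * (x / sig_post**2) * norm.pdf(x, 0, sig_post) * grid.cell_measure
        assert np.corrcoef(fd, analytic)[0, 1] > 0.99999
        assert np.linalg.norm(fd - analytic) / np.linalg.norm(analytic) < 1e-3

    def test_richardson_order_of_accuracy(self):
        grid = LatentGrid(bounds=((-6.0, 6.0),), bins_per_dim=201)
        x = grid.cell_centers[:, 0]
        prior = ProbabilityField(grid, norm.pdf(x, 0, 1.5) * grid.cell_measure).normalize()

        def post_mass(s):
            m = prior.mass * norm.pdf(s, x, 0.8)
            return m / m.sum()

        def fd(delta):
            return (post_mass(delta) - post_mass(-delta)) / (2 * delta)

        err_big = np.linalg.norm(fd(0.2) - fd(1e-4))
        err_small = np.linalg.norm(fd(0.1) - fd(1e-4))
        assert err_big / err_small == pytest.approx(4.0, rel=0.2)

    def test_belief_derivative_zero_for_identical_priors(self, grid3, field3):
        brain = BrainModel(grid3, sigma_e_sq=0.5)
        priors = TaskPriors(p1=field3, p2=field3)
        d = dposterior_dpi(brain, [1.0], priors, method="analytic")
        assert np.allclose(d.delta_mass, 0)

    def test_belief_derivative_analytic_matches_finite_difference(self, grid3):
        brain = BrainModel(grid3, sigma_e_sq=0.4)
        p1 = ProbabilityField(grid3, np.array([0.7, 0.2, 0.1]), normalized=True)
        p2 = ProbabilityField(grid3, np.array([0.1, 0.1, 0.8]), normalized=True)
        priors = TaskPriors(p1=p1, p2=p2)
        ana = dposterior_dpi(brain, [1.4], priors, method="analytic")
        err = []
        for h in (0.02, 0.01):
            fd = dposterior_dpi(brain, [1.4], priors, delta_pi=h, method="fd")
            err.append(np.linalg.norm(fd.delta_mass - ana.delta_mass))
            assert abs(fd.delta_mass.sum()) < 1e-8
        assert err[0] / err[1] == pytest.approx(4.0, rel=0.3)  # O(h^2)

    def test_belief_step_outside_unit_interval_errors(self, grid3, field3):
        brain = BrainModel(grid3, sigma_e_sq=0.5)
        priors = TaskPriors(p1=field3, p2=field3)
        with pytest.raises(ValueError):
            dposterior_dpi(brain, [1.0], priors, delta_pi=0.6, method="fd")

    @pytest.mark.parametrize(
        "b,expected", [(+1.0, 1.0), (-1.0, -1.0)]
    )
    def test_alignment_reference_points(self, grid3, b, expected):
        v = np.array([1.0, -2.0, 1.0])
        a = PosteriorDerivative(grid3, v, wrt="s", step=0.1)
        c = PosteriorDerivative(grid3, b * v, wrt="pi", step=0.1)
        assert alignment(a, c) == pytest.approx(expected)


class TestSelfConsistency:
    def test_prior_equals_average_posterior_at_fixed_point(self, imprecise_brain):
        exp = zero_noise_exp()
        exp = type(exp)(
            stimulus_dist=delta_mixture_ensemble(0.5, 0.5),
            coding_mode="mean_coded",
        )
        out = subthreshold_analysis(imprecise_brain, exp, n_draws=600, rng=0)
        brain = imprecise_brain.with_prior(out["prior"])
        # average posterior over the ensemble, fresh code path
        from beliefcov.inference import average_posterior

        atoms, w = exp.stimulus_dist.atoms()
        avg = average_posterior(brain, exp, atoms, w, 600, rng=0)
        tv = 0.5 * np.abs(avg.mass - out["prior"].mass).sum()
        assert tv < 0.05

    def test_category_label_swap_flips_belief_derivative(self, imprecise_brain):
        exp = zero_noise_exp()
        out = subthreshold_analysis(imprecise_brain, exp, rng=0)
        swapped = TaskPriors(p1=out["priors"].p2, p2=out["priors"].p1)
        d = dposterior_dpi(
            imprecise_brain.with_prior(out["prior"]),
            np.zeros(2), swapped, method="analytic",
        )
        cos = alignment(out["d_s"], d)
        cos_orig = alignment(out["d_s"], out["d_pi"])
        assert cos == pytest.approx(-cos_orig, abs=1e-6)


class TestCategoryDecoder:
    def test_boundary_cells_are_maximally_uncertain(self, imprecise_brain, mean_exp):
        dec = category_decoder(imprecise_brain, mean_exp)
        grid = imprecise_brain.grid
        assert np.all((dec >= 0) & (dec <= 1))
        # cells on the boundary column (x1 = 0) decode to exactly 1/2, the
        # symmetric task gives dec(x) + dec(-x) = 1 everywhere, and the
        # decoder increases with x1 along the stimulus axis
        center = np.all(grid.cell_centers == 0.0, axis=1)
        assert np.abs(dec[center] - 0.5).max() < 1e-8
        assert np.allclose(dec + dec[::-1], 1.0, atol=1e-8)
        axis_row = grid.cell_centers[:, 1] == 0.0
        assert np.all(np.diff(dec[axis_row]) >= -1e-12)

    def test_matches_bruteforce_joint_on_coarse_grid(self):
        grid = LatentGrid(bounds=((-5.0, 5.0),) * 2, bins_per_dim=7)
        brain = BrainModel(grid, sigma_e_sq=0.36)
        exp = zero_noise_exp(ensemble=delta_mixture_ensemble(0.4, 1.0))
        dec = category_decoder(brain, exp)
        # brute force: enumerate the three atoms and both categories
        from beliefcov import experimenter_mean, likelihood_values

        num = np.zeros(grid.n_cells)
        den = np.zeros(grid.n_cells)
        for s, w in zip([-1.0, 0.0, 1.0], [0.3, 0.4, 0.3]):
            L = likelihood_values(brain, experimenter_mean(exp, s).reshape(1, -1))[0]
            pc1 = 1.0 if s > 0 else (0.0 if s < 0 else 0.5)
            num += w * pc1 * L
            den += w * L
        assert np.allclose(dec, num / den, atol=1e-12)


class TestProportionality:
    def test_gaussian_demo_improves_as_categories_merge(self, grid1d):
        cos = [
            gaussian_mixture_demo(mu, grid=grid1d)["cosine"]
            for mu in (2.0, 1.0, 0.5, 0.25)
        ]
        assert np.all(np.diff(cos) > 0)
        assert cos[-1] > 0.999

    def test_cosine_degrades_with_larger_category_offset(self, precise_brain):
        """With observation noise, the stimulus/belief symmetry weakens
        monotonically as the category offset leaves the sub-threshold
        regime."""
        from beliefcov import ExperimenterModel

        cosines = []
        for ds in (0.01, 1.5):
            exp = ExperimenterModel(
                stimulus_dist=delta_mixture_ensemble(0.5, ds),
                coding_mode="mean_coded",
            )
            out = subthreshold_analysis(precise_brain, exp, n_draws=600, rng=3)
            cosines.append(out["cosine"])
        assert cosines[0] > cosines[1] + 0.05
        # and the zero-noise sub-threshold limit is near-perfect
        out0 = subthreshold_analysis(
            precise_brain, zero_noise_exp(ensemble=delta_mixture_ensemble(0.9, 0.01)),
            rng=0,
        )
        assert out0["cosine"] > 0.99
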