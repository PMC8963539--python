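import numpy as np
import pytest

from beliefcov import (
    belief_feedback_demo,
    choice_probability,
    covariance_decomposition,
    cosine_similarity,
    cp_dprime_relation,
    cta,
    dprime_vector,
    simulate_session,
)
from beliefcov.codes import mean_rates
from beliefcov.neurometrics import TrialSet

# One reduced-scale session setup shared by the whole module; the
# full-strength configuration is exercised by the acceptance suite.
DEMO = belief_feedback_demo(n_neurons=48, gain=600.0, bins_per_dim=15, n_draws=800)


def _session(var_pi, n_trials=6000, rng=0):
    return simulate_session(
        DEMO["brain"], DEMO["exp_session"], DEMO["code"], DEMO["priors"],
        var_pi=var_pi, n_trials=n_trials, rng=rng,
    )


class TestSimulateSession:
    def test_zero_belief_variance_gives_balanced_coin_choices(self):
        ts = _session(0.0, n_trials=4000, rng=1)
        assert np.all(ts.pi == 0.5)
        frac = np.mean(ts.choices == 1)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_choice_frequencies_balanced_for_symmetric_beliefs(self):
        ts = _session(0.04, n_trials=4000, rng=2)
        assert abs(np.mean(ts.choices == 1) - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_mean_response_matches_tuning_at_zero_signal(self):
        ts = _session(0.0, n_trials=6000, rng=3)
        f0 = mean_rates(
            DEMO["code"],
            # posterior at s=0 under the pi=1/2 mixture prior
            __import__("beliefcov").posterior_given_belief(
                DEMO["brain"], DEMO["exp_session"].mean(0.0), 0.5, DEMO["priors"]
            ),
        )
        se = ts.responses.std(axis=0, ddof=1) / np.sqrt(len(ts.s))
        assert np.all(np.abs(ts.responses.mean(axis=0) - f0) < 4 * se + 1e-9)

    def test_negative_variance_errors(self):
        with pytest.raises(ValueError):
            _session(-0.1)


class TestCta:
    def test_zero_belief_variance_gives_null_cta(self):
        ts = _session(0.0, rng=4)
        r1 = ts.responses[ts.choices == 1]
        r2 = ts.responses[ts.choices == 2]
        se = np.sqrt(r1.var(0) / len(r1) + r2.var(0) / len(r2))
        assert np.all(np.abs(cta(ts)) < 4 * se + 1e-9)

    def test_choice_relabeling_negates_cta(self):
        ts = _session(0.04, rng=5)
        flipped = TrialSet(
            s=ts.s, pi=ts.pi, responses=ts.responses, choices=3 - ts.choices,
            var_pi=ts.var_pi, code_kind=ts.code_kind, seed=ts.seed,
        )
        assert np.allclose(cta(flipped), -cta(ts))

    def test_cta_aligns_with_fprime_under_belief_feedback(self):
        ts = _session(0.04, n_trials=10_000, rng=6)
        assert cosine_similarity(cta(ts), DEMO["tuning"].fprime) > 0.9

    def test_single_choice_session_errors(self):
        ts = _session(0.0, n_trials=100, rng=7)
        one_sided = TrialSet(
            s=ts.s, pi=ts.pi, responses=ts.responses,
            choices=np.ones(len(ts.s), dtype=int), var_pi=0.0,
            code_kind=ts.code_kind, seed=0,
        )
        with pytest.raises(ValueError):
            cta(one_sided)


class TestChoiceProbability:
    def test_choice_independent_responses_give_half(self):
        ts = _session(0.0, rng=8)
        cp = choice_probability(ts)
        assert np.abs(cp - 0.5).mean() < 0.02

    def test_perfect_separation_gives_one(self, grid3):
        responses = np.array([[10.0], [10.0], [0.0], [0.0]])
        ts = TrialSet(
            s=np.zeros(4), pi=np.array([0.9, 0.8, 0.1, 0.2]),
            responses=responses, choices=np.array([1, 1, 2, 2]),
            var_pi=0.1, code_kind="linear_moment", seed=0,
        )
        assert choice_probability(ts)[0] == pytest.approx(1.0)

    def test_matches_quadratic_pairwise_oracle(self):
        ts = _session(0.04, n_trials=300, rng=9)
        cp = choice_probability(ts)
        r1 = ts.responses[ts.choices == 1]
        r2 = ts.responses[ts.choices == 2]
        wins = (r1[:, None, :] > r2[None, :, :]).sum(axis=(0, 1))
        ties = (r1[:, None, :] == r2[None, :, :]).sum(axis=(0, 1))
        oracle = (wins + 0.5 * ties) / (len(r1) * len(r2))
        assert np.allclose(cp, oracle, atol=1e-12)

    def test_invariant_to_monotone_response_transform(self):
        ts = _session(0.04, n_trials=500, rng=10)
        warped = TrialSet(
            s=ts.s, pi=ts.pi, responses=np.log1p(ts.responses.astype(float)),
            choices=ts.choices, var_pi=ts.var_pi, code_kind=ts.code_kind, seed=ts.seed,
        )
        assert np.allclose(choice_probability(ts), choice_probability(warped))


class TestDprime:
    def test_sign_matches_fprime_and_flat_neurons_are_zero(self):
        tun = DEMO["tuning"]
        d = dprime_vector(tun)
        strong = np.abs(tun.fprime) > 1e-3
        assert np.all(np.sign(d[strong]) == np.sign(tun.fprime[strong]))

    def test_poisson_gain_scaling(self):
        """Doubling the gain of a linear Poisson code scales d' by sqrt(2)."""
        from beliefcov import DistributionalCode, tuning_curve

        base = DEMO["code"]
        doubled = DistributionalCode(
            kind=base.kind, weights=base.weights, gain=2 * base.gain,
            baseline=2 * base.baseline, k_samples=base.k_samples,
        )
        kw = dict(
            s_values=np.linspace(-2, 2, 5), priors=DEMO["priors"],
            delta_s=0.5, n_draws=4000, rng=11,
        )
        t1 = tuning_curve(base, DEMO["brain"], DEMO["exp_session"], **kw)
        t2 = tuning_curve(doubled, DEMO["brain"], DEMO["exp_session"], **kw)
        strong = np.abs(t1.fprime) > np.percentile(np.abs(t1.fprime), 75)
        ratio = np.median(t2.dprime()[strong] / t1.dprime()[strong])
        assert ratio == pytest.approx(np.sqrt(2), rel=0.1)


class TestCpDprimeRelation:
    def test_belief_feedback_couples_cp_to_dprime(self):
        ts = _session(0.04, n_trials=10_000, rng=12)
        assert cp_dprime_relation(ts, DEMO["tuning"]) > 0.8

    def test_requires_enough_neurons(self):
        ts = _session(0.04, n_trials=200, rng=13)
        small = TrialSet(
            s=ts.s, pi=ts.pi, responses=ts.responses[:, :10],
            choices=ts.choices, var_pi=ts.var_pi, code_kind=ts.code_kind, seed=ts.seed,
        )
        tun = DEMO["tuning"]
        from beliefcov.codes import TuningCurve

        tun10 = TuningCurve(
            s_values=tun.s_values, rates=tun.rates[:10],
            fprime=tun.fprime[:10], sigma=tun.sigma[:10],
        )
        with pytest.raises(ValueError):
            cp_dprime_relation(small, tun10)


class TestCovarianceDecomposition:
    def test_null_belief_variance_gives_null_belief_component(self):
        ts_a = _session(0.0, n_trials=8000, rng=14)
        ts_b = _session(0.0, n_trials=8000, rng=15)
        dec = covariance_decomposition(ts_a, ts_b, DEMO["tuning"])
        # the difference of two matched null covariances is pure noise
        noise_scale = np.linalg.norm(dec.sigma_intrinsic, "fro")
        assert np.linalg.norm(dec.sigma_belief, "fro") < 0.2 * noise_scale

    def test_requires_matched_null_session(self):
        ts1 = _session(0.04, n_trials=1000, rng=16)
        with pytest.raises(ValueError):
            covariance_decomposition(ts1, ts1, DEMO["tuning"])

    def test_belief_component_is_rank_one_along_fprime(self):
        ts1 = _session(0.01, n_trials=20_000, rng=17)
        ts0 = _session(0.0, n_trials=20_000, rng=18)
        dec = covariance_decomposition(ts1, ts0, DEMO["tuning"])
        assert dec.alignment > 0.95
        assert dec.top_eigenvalue > 0
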