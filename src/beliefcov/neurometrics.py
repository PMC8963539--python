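"""Decision-related statistics: CTA, choice probability, d', covariance split.

Sessions consist of zero-signal trials (s = 0) on which the observer's
categorical belief pi fluctuates around 1/2.  Belief feedback moves the
posterior along dp/dpi, hence (for a self-consistent observer and a linear
distributional code) moves firing rates along f'.  Consequences tested here:

* the choice-triggered average CTA_i is proportional to f'_i;
* choice probability satisfies CP_i - 1/2 ~ d'_i = f'_i / sigma_i;
* the belief component of the noise covariance is the rank-one matrix
  var(pi) alpha^2 f' f'^T, isolated as Sigma_total - Sigma_intrinsic between
  matched sessions with and without belief variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .codes import DistributionalCode, sample_responses
from .grid import cosine_similarity
from .inference import TaskPriors
from .codes import TuningCurve
from .stimuli import sample_beliefs
from .world import BrainModel, ExperimenterModel, likelihood_values, sample_observation

__all__ = [
    "TrialSet",
    "CovarianceDecomposition",
    "belief_feedback_demo",
    "simulate_session",
    "cta",
    "choice_probability",
    "dprime_vector",
    "cp_dprime_relation",
    "covariance_decomposition",
]


def belief_feedback_demo(
    n_neurons: int = 128,
    gain: float = 1600.0,
    baseline: float = 0.5,
    bump_width: float = 0.5,
    bins_per_dim: int = 21,
    delta_s: float = 1.5,
    p0: float = 0.2,
    sigma_e_sq: float = 0.36,
    n_draws: int = 2000,
    rng: np.random.Generator | int = 1,
) -> dict:
    """Canonical belief-feedback session setup.

    A coarse two-category task on a straight discrimination axis
    (E(s) = (s, 0)) with observation noise 0.5 I during learning; the
    observer's category priors are the self-consistent noise-averaged
    posteriors at the two discriminanda.  Sessions are then run at s = 0
    with *no* shared observation noise, so the only trial-to-trial
    covariability is belief feedback plus private Poisson spiking — the
    regime in which CTA ~ f', CP - 1/2 ~ d', and the rank-one belief
    covariance are cleanly expressed.

    Returns a dict with the brain (self-consistent prior installed), the
    noisy construction model, the noiseless session model, the category
    priors, the distributional code, and the tuning curve.
    """
    from .codes import make_code, tuning_curve
    from .grid import LatentGrid
    from .inference import subthreshold_analysis
    from .stimuli import delta_mixture_ensemble
    from .world import ExperimenterModel

    rng = np.random.default_rng(rng)
    grid = LatentGrid(bounds=((-5.0, 5.0), (-5.0, 5.0)), bins_per_dim=bins_per_dim)
    brain = BrainModel(grid, sigma_e_sq=sigma_e_sq)
    axis = lambda s: np.array([s, 0.0])  # noqa: E731
    exp_noisy = ExperimenterModel(
        stimulus_dist=delta_mixture_ensemble(p0, delta_s),
        coding_mode="custom", mean_fn=axis, cov_fn=lambda s: 0.5 * np.eye(2),
    )
    exp_session = ExperimenterModel(
        stimulus_dist=delta_mixture_ensemble(p0, delta_s),
        coding_mode="custom", mean_fn=axis, cov_fn=lambda s: np.zeros((2, 2)),
    )
    sub = subthreshold_analysis(brain, exp_noisy, n_draws=n_draws, rng=rng)
    brain = brain.with_prior(sub["prior"])
    code = make_code(
        "linear_moment", grid, n_neurons=n_neurons, gain=gain,
        baseline=baseline, bump_width=bump_width,
    )
    tuning = tuning_curve(
        code, brain, exp_session, s_values=np.linspace(-2, 2, 9),
        priors=sub["priors"], delta_s=delta_s / 3, n_draws=500,
        rng=int(rng.integers(2**31)),
    )
    return dict(
        brain=brain,
        exp_learning=exp_noisy,
        exp_session=exp_session,
        priors=sub["priors"],
        code=code,
        tuning=tuning,
        d_pi=sub["d_pi"],
        d_s=sub["d_s"],
    )


@dataclass
class TrialSet:
    """Per-trial records of a simulated zero-signal session."""

    s: np.ndarray
    pi: np.ndarray
    responses: np.ndarray  # (n_trials, n_neurons)
    choices: np.ndarray  # 1 where pi > 1/2 (ties: fair coin)
    var_pi: float
    code_kind: str
    seed: int

    def __post_init__(self) -> None:
        n = len(self.s)
        if not (len(self.pi) == len(self.choices) == self.responses.shape[0] == n):
            raise ValueError("inconsistent trial counts")
        if not np.all(np.isin(self.choices, (1, 2))):
            raise ValueError("choices must be 1 or 2")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]


def simulate_session(
    brain: BrainModel,
    exp: ExperimenterModel,
    code: DistributionalCode,
    priors: TaskPriors,
    var_pi: float,
    n_trials: int,
    rng: np.random.Generator | int = 0,
) -> TrialSet:
    """Zero-signal session with per-trial belief draws and spiking responses.

    Each trial: pi ~ Beta(a, a) with variance var_pi; E ~ p_e(E|s=0); the
    response is sampled from the code applied to p_b(x | E, pi); the choice
    is category 1 when pi > 1/2 (ties broken by a fair coin).
    """
    if var_pi < 0:
        raise ValueError("var_pi must be nonnegative")
    seed = int(np.random.default_rng(rng).integers(2**31))
    rng = np.random.default_rng(seed)
    pi = sample_beliefs(var_pi, n_trials, rng)
    deterministic = np.allclose(exp.cov(0.0), 0)
    if deterministic:
        E = np.tile(sample_observation(exp, 0.0, rng), (n_trials, 1))
    else:
        E = sample_observation(exp, 0.0, rng, size=n_trials)
    L = likelihood_values(brain, E)
    prior_rows = pi[:, None] * priors.p1.mass[None, :] + (1 - pi)[:, None] * priors.p2.mass[None, :]
    post = L * prior_rows
    post /= post.sum(axis=1, keepdims=True)
    responses = sample_responses(code, post, rng)
    choices = np.where(pi > 0.5, 1, 2)
    ties = pi == 0.5
    choices[ties] = rng.choice([1, 2], size=ties.sum())
    return TrialSet(
        s=np.zeros(n_trials),
        pi=pi,
        responses=responses,
        choices=choices,
        var_pi=var_pi,
        code_kind=code.kind,
        seed=seed,
    )


def _split_by_choice(trials: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    r1 = trials.responses[trials.choices == 1]
    r2 = trials.responses[trials.choices == 2]
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("both choices must be present")
    return r1, r2


def cta(trials: TrialSet) -> np.ndarray:
    """Choice-triggered average: mean response difference, choice 1 - choice 2."""
    r1, r2 = _split_by_choice(trials)
    return r1.mean(axis=0) - r2.mean(axis=0)


def choice_probability(trials: TrialSet) -> np.ndarray:
    """Per-neuron area under the ROC separating choice-conditioned responses.

    Rank-statistic (Mann-Whitney) implementation with midrank tie handling;
    0.5 means no choice association, 1.0 perfect separation with choice-1
    responses larger.  Invariant to monotone transforms of the responses.
    """
    r1, r2 = _split_by_choice(trials)
    n1, n2 = len(r1), len(r2)
    stacked = np.concatenate([r1, r2], axis=0)
    ranks = rankdata(stacked, axis=0)
    rank_sum_1 = ranks[:n1].sum(axis=0)
    u1 = rank_sum_1 - n1 * (n1 + 1) / 2.0
    return u1 / (n1 * n2)


def dprime_vector(tuning: TuningCurve) -> np.ndarray:
    """Neurometric sensitivity d'_i = f'_i / sigma_i."""
    return tuning.dprime()


def cp_dprime_relation(trials: TrialSet, tuning: TuningCurve) -> float:
    """Pearson correlation across neurons between (CP - 1/2) and d'."""
    if trials.n_neurons < 20:
        raise ValueError("need at least 20 neurons for a stable correlation")
    cp = choice_probability(trials) - 0.5
    dp = dprime_vector(tuning)
    if np.std(cp) == 0 or np.std(dp) == 0:
        raise ValueError("degenerate variance in CP or d-prime")
    return float(np.corrcoef(cp, dp)[0, 1])


@dataclass
class CovarianceDecomposition:
    """Total/intrinsic/belief covariance split with f'-alignment summary."""

    sigma_total: np.ndarray
    sigma_intrinsic: np.ndarray
    sigma_belief: np.ndarray
    fprime: np.ndarray
    var_pi: float
    alignment: float
    top_eigenvalue: float
    fitted_scale: float  # top eigenvalue / |f'|^2 = empirical var(pi) alpha^2


def covariance_decomposition(
    trials_with: TrialSet,
    trials_without: TrialSet,
    tuning: TuningCurve,
) -> CovarianceDecomposition:
    """Isolate the belief component of the noise covariance.

    ``trials_with`` has var(pi) > 0; ``trials_without`` is a matched session
    with var(pi) = 0 supplying the intrinsic covariance.  The difference is
    predicted to be approximately rank one along f' f'^T with magnitude
    proportional to var(pi).
    """
    if trials_without.var_pi != 0:
        raise ValueError("the reference session must have var_pi = 0")
    if trials_with.n_neurons != trials_without.n_neurons:
        raise ValueError("sessions must share the neural population")
    for t in (trials_with, trials_without):
        if len(t.s) < 10 * t.n_neurons:
            raise ValueError("too few trials for a stable covariance estimate")
    sigma_total = np.cov(trials_with.responses, rowvar=False)
    sigma_intrinsic = np.cov(trials_without.responses, rowvar=False)
    sigma_belief = sigma_total - sigma_intrinsic
    vals, vecs = np.linalg.eigh(sigma_belief)
    top = vecs[:, -1]
    fprime = tuning.fprime
    align = abs(cosine_similarity(top, fprime))
    return CovarianceDecomposition(
        sigma_total=sigma_total,
        sigma_intrinsic=sigma_intrinsic,
        sigma_belief=sigma_belief,
        fprime=fprime,
        var_pi=trials_with.var_pi,
        alignment=align,
        top_eigenvalue=float(vals[-1]),
        fitted_scale=float(vals[-1] / (fprime @ fprime)),
    )
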