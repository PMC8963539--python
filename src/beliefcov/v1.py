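"""Sampling-based sparse-coding V1 model under cued task switching.

A population of orientation-tuned neurons performs inference in a linear
sparse-coding model of small image patches: the image is y = A z + pixel
noise, with nonnegative intensities z and oriented-grating projective fields
A.  The task alternates between two contexts — cardinal (0 vs 90 deg) and
oblique (45 vs 135 deg) — signalled by a pre-trial cue that is correct only
80% of the time.  The context shapes the prior over intensities: the grating
hypothesis G currently entertained boosts the expected intensity of neurons
preferring nearby orientations.

Responses are sums of Gibbs samples of each neuron's intensity on
zero-signal (white-noise) trials.  Because the sampler's belief about G
fluctuates across trials, the noise-correlation matrix acquires low-rank
structure along the two tasks' discrimination axes (difference of
orientation bumps), on top of smooth stimulus-driven components that form
sinusoidal quadrature pairs in preferred orientation.  An eigenvector
analysis of the noise correlations therefore reads out the observer's
internal task beliefs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

__all__ = [
    "V1Model",
    "BeliefSpectrum",
    "simulate_v1_session",
    "noise_correlation",
    "belief_spectrum",
    "task_fprime_template",
]

logger = logging.getLogger(__name__)

CONTEXTS = {"cardinal": (0.0, 90.0), "oblique": (45.0, 135.0)}


@dataclass(frozen=True)
class V1Model:
    """Linear sparse-coding model with context-dependent intensity priors.

    Parameters
    ----------
    n_neurons :
        Population size; preferred orientations tile [0, 180) uniformly.
    patch_size :
        Side of the square image patch in pixels.
    spatial_freq :
        Grating frequency of the projective fields, cycles per patch.
    pixel_noise_sd :
        Assumed pixel noise SD of the internal model (likelihood width).
    stimulus_sd :
        SD of the white-noise images shown on zero-signal trials.
    base_intensity, boost_intensity :
        Exponential-prior mean intensity far from / at the entertained
        grating orientation; the boost has angular width ``boost_width_deg``.
    cue_reliability :
        Probability that the pre-trial cue indicates the true context.
    """

    n_neurons: int = 1024
    patch_size: int = 16
    spatial_freq: float = 2.0
    envelope_sigma: float = 0.2  # Gaussian envelope SD, fraction of patch
    pixel_noise_sd: float = 0.4
    stimulus_sd: float = 0.5
    base_intensity: float = 0.2
    boost_intensity: float = 1.0
    boost_width_deg: float = 8.0
    cue_reliability: float = 0.8
    burn_in: int = 10
    samples_per_trial: int = 20

    def __post_init__(self) -> None:
        if not 0.5 < self.cue_reliability <= 1.0:
            raise ValueError("cue_reliability must lie in (0.5, 1]")
        if self.n_neurons < 4 or self.patch_size < 2:
            raise ValueError("population or patch too small")

    @property
    def orientations(self) -> np.ndarray:
        """Preferred orientations in degrees, uniform on [0, 180)."""
        return np.arange(self.n_neurons) * 180.0 / self.n_neurons

    @property
    def grating_orientations(self) -> np.ndarray:
        """The four grating hypotheses entertained across the two contexts."""
        return np.array([0.0, 90.0, 45.0, 135.0])

    def projective_fields(self) -> np.ndarray:
        """Unit-norm oriented gratings, shape (n_neurons, n_pixels)."""
        return np.stack([self._grating(th) for th in self.orientations])

    def _grating(self, theta_deg: float, phase: float = 0.0) -> np.ndarray:
        p = self.patch_size
        coords = (np.arange(p) - (p - 1) / 2) / p
        xx, yy = np.meshgrid(coords, coords)
        th = np.deg2rad(theta_deg)
        wave = np.cos(
            2 * np.pi * self.spatial_freq * (xx * np.cos(th) + yy * np.sin(th)) + phase
        )
        envelope = np.exp(-0.5 * (xx**2 + yy**2) / self.envelope_sigma**2)
        g = (wave * envelope).ravel()
        return g / np.linalg.norm(g)

    def prior_rates(self) -> np.ndarray:
        """Exponential-prior rates lambda_i(G), shape (4, n_neurons)."""
        theta = self.orientations
        rates = np.empty((4, self.n_neurons))
        for k, phi in enumerate(self.grating_orientations):
            d = _angle_diff(theta, phi)
            mean = self.base_intensity + self.boost_intensity * np.exp(
                -0.5 * (d / self.boost_width_deg) ** 2
            )
            rates[k] = 1.0 / mean
        return rates

    def cue_log_prior(self, cue_is_cardinal: np.ndarray) -> np.ndarray:
        """log p(G | cue) per trial, shape (n_trials, 4)."""
        r = self.cue_reliability
        cue_is_cardinal = np.asarray(cue_is_cardinal, dtype=bool)
        pc = np.where(cue_is_cardinal, r / 2, (1 - r) / 2)  # each cardinal grating
        po = np.where(cue_is_cardinal, (1 - r) / 2, r / 2)  # each oblique grating
        return np.log(np.maximum(np.column_stack([pc, pc, po, po]), 1e-300))


def _angle_diff(a: np.ndarray, b: float) -> np.ndarray:
    """Orientation difference on the 180-degree circle, in [0, 90]."""
    d = np.abs(np.asarray(a) - b) % 180.0
    return np.minimum(d, 180.0 - d)


def _sample_lower_truncated_normal(
    mu: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draws from N(mu, sigma^2) truncated to [0, inf), vectorized.

    Inverse-CDF in the upper tail for numerical stability when mu << 0.
    """
    from scipy.special import ndtr

    a = -mu / sigma  # standardized lower bound
    tail = ndtr(-a)  # P(X > a)
    u = rng.random(mu.shape)
    arg = np.maximum(u * tail, 1e-300)
    x = -ndtri(arg)
    return mu + sigma * np.where(np.isfinite(x), x, a)  # degenerate tail -> bound


def simulate_v1_session(
    model: V1Model,
    n_trials: int,
    rng: np.random.Generator | int = 0,
    images: np.ndarray | None = None,
    cue_is_cardinal: np.ndarray | None = None,
    return_diagnostics: bool = False,
):
    """Gibbs-sample intensity posteriors on white-noise trials.

    Per trial: a context cue (cardinal/oblique, correct with probability
    ``cue_reliability``), a white-noise image, and a Gibbs chain over the
    grating hypothesis G and the nonnegative intensity vector z.  The
    response matrix is the per-neuron sum of intensity samples after burn-in,
    shape (n_trials, n_neurons).  All trials are advanced in parallel.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(rng)
    A = model.projective_fields()  # (N, P)
    N, P = A.shape
    rates = model.prior_rates()  # (4, N)
    sig2 = model.pixel_noise_sd**2

    if images is None:
        images = rng.normal(0.0, model.stimulus_sd, size=(n_trials, P))
    if cue_is_cardinal is None:
        # The session's true context is cardinal; the pre-trial cue reports
        # it with probability cue_reliability (80/20 by default), so the
        # wrong-task (oblique) prior is engaged on the miscued trials.
        cue_is_cardinal = rng.random(n_trials) < model.cue_reliability
    log_cue = model.cue_log_prior(np.asarray(cue_is_cardinal))

    Z = np.zeros((n_trials, N))
    G = np.argmax(log_cue + rng.gumbel(size=(n_trials, 4)), axis=1)
    residual = images - Z @ A  # (n_trials, P)
    responses = np.zeros((n_trials, N))
    g_counts = np.zeros((n_trials, 4))
    autocorr_num = np.zeros(N)
    prev_Z = None

    total_sweeps = model.burn_in + model.samples_per_trial
    for sweep in range(total_sweeps):
        for i in range(N):
            a_i = A[i]
            b = residual @ a_i + Z[:, i]  # since |a_i| = 1
            lam_i = rates[G, i]
            mu = b - lam_i * sig2
            z_new = _sample_lower_truncated_normal(mu, model.pixel_noise_sd, rng)
            residual += np.outer(Z[:, i] - z_new, a_i)
            Z[:, i] = z_new
        # Resample the grating hypothesis given the intensities.
        loglik = np.log(rates).sum(axis=1)[None, :] - Z @ rates.T  # (n_trials, 4)
        logpost = loglik + log_cue
        G = np.argmax(logpost + rng.gumbel(size=(n_trials, 4)), axis=1)
        if sweep >= model.burn_in:
            responses += Z
            g_counts[np.arange(n_trials), G] += 1
            if prev_Z is not None:
                autocorr_num += (prev_Z * Z).sum(axis=0)
            prev_Z = Z.copy()

    if not return_diagnostics:
        return responses
    diag = dict(
        g_frequencies=g_counts / model.samples_per_trial,
        cue_is_cardinal=np.asarray(cue_is_cardinal),
        mean_within_trial_autocorr=float(
            autocorr_num.sum() / max(1, (model.samples_per_trial - 1) * n_trials)
        ),
    )
    return responses, diag


def noise_correlation(counts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of trial-by-neuron counts.

    Zero-variance neurons are excluded (their rows/columns are set to 0 with
    unit diagonal) with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    var = counts.var(axis=0)
    bad = var <= 0
    if bad.any():
        logger.warning("excluding %d zero-variance neurons", int(bad.sum()))
    corr = np.eye(counts.shape[1])
    good = ~bad
    sub = np.corrcoef(counts[:, good], rowvar=False)
    corr[np.ix_(good, good)] = sub
    return corr


@dataclass
class BeliefSpectrum:
    """Eigenstructure of the noise-correlation matrix with belief labels."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns match eigenvalues
    significant: np.ndarray  # boolean per component
    labels: list
    n_significant: int
    shuffle_floor: np.ndarray  # per-rank 95th percentile of shuffled spectra
    sensitivity: dict  # n_significant under alternative criteria
    template_cosines: np.ndarray  # (n_components, 2): cardinal, oblique


def belief_spectrum(
    counts: np.ndarray,
    preferred_orientations: np.ndarray,
    n_shuffles: int = 100,
    rng: np.random.Generator | int = 0,
    templates: dict | None = None,
    belief_cosine_threshold: float = 0.8,
) -> BeliefSpectrum:
    """Eigen-decompose noise correlations and label belief components.

    Significance follows a parallel-analysis criterion: component k is a
    candidate when its eigenvalue exceeds the 95th percentile of the k-th
    eigenvalue across ``n_shuffles`` trial-shuffled (per-neuron independent
    permutation) datasets; components are counted from the top until the
    first non-significant one.  Sensitivity of the count to the percentile
    (90/95/99) and to a max-eigenvalue floor is reported.

    Belief components are identified by cosine similarity with the two task
    templates (difference of orientation bumps at each context's two
    discriminanda); remaining significant components with a predominantly
    sinusoidal profile in preferred orientation are labelled stimulus-driven.
    """
    rng = np.random.default_rng(rng)
    counts = np.asarray(counts, dtype=float)
    n_trials, n_neurons = counts.shape
    corr = noise_correlation(counts)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    shuffled_vals = np.empty((n_shuffles, n_neurons))
    for k in range(n_shuffles):
        perm = counts.copy()
        for j in range(n_neurons):
            rng.shuffle(perm[:, j])
        sv = np.linalg.eigvalsh(noise_correlation(perm))
        shuffled_vals[k] = sv[::-1]
    floors = {p: np.percentile(shuffled_vals, p, axis=0) for p in (90, 95, 99)}

    def count_from_top(floor: np.ndarray) -> int:
        above = vals > floor
        n = 0
        while n < n_neurons and above[n]:
            n += 1
        return n

    n_sig = count_from_top(floors[95])
    sensitivity = {
        "percentile_90": count_from_top(floors[90]),
        "percentile_95": n_sig,
        "percentile_99": count_from_top(floors[99]),
        "max_eigenvalue_floor": int(
            np.argmin(vals > np.percentile(shuffled_vals[:, 0], 95))
            if not (vals > np.percentile(shuffled_vals[:, 0], 95)).all()
            else n_neurons
        ),
    }
    significant = np.zeros(n_neurons, dtype=bool)
    significant[:n_sig] = True

    if templates is None:
        templates = {
            name: _bump_difference_template(preferred_orientations, phis)
            for name, phis in CONTEXTS.items()
        }
    t_card = templates["cardinal"] / np.linalg.norm(templates["cardinal"])
    t_obl = templates["oblique"] / np.linalg.norm(templates["oblique"])
    template_cos = np.stack(
        [vecs.T @ t_card, vecs.T @ t_obl], axis=1
    )

    labels = []
    for k in range(n_neurons):
        if not significant[k]:
            labels.append("noise")
            continue
        c_card, c_obl = np.abs(template_cos[k])
        if c_card >= belief_cosine_threshold and c_card >= c_obl:
            labels.append("cardinal_belief")
        elif c_obl >= belief_cosine_threshold:
            labels.append("oblique_belief")
        elif _sinusoid_r2(preferred_orientations, vecs[:, k]) > 0.6:
            labels.append("stimulus_driven")
        else:
            labels.append("noise")
    return BeliefSpectrum(
        eigenvalues=vals,
        eigenvectors=vecs,
        significant=significant,
        labels=labels,
        n_significant=n_sig,
        shuffle_floor=floors[95],
        sensitivity=sensitivity,
        template_cosines=template_cos,
    )


def _bump_difference_template(theta: np.ndarray, phis, width: float = 8.0) -> np.ndarray:
    """Difference of Gaussian orientation bumps at the two discriminanda."""
    b1 = np.exp(-0.5 * (_angle_diff(theta, phis[0]) / width) ** 2)
    b2 = np.exp(-0.5 * (_angle_diff(theta, phis[1]) / width) ** 2)
    t = b1 - b2
    return t - t.mean()


def _sinusoid_r2(theta: np.ndarray, v: np.ndarray, max_freq: int = 6) -> float:
    """Best single-frequency sinusoidal fit quality of an eigenvector."""
    v = v - v.mean()
    tot = float(v @ v)
    if tot == 0:
        return 0.0
    best = 0.0
    ang = np.deg2rad(theta) * 2  # orientation domain has period 180 deg
    for k in range(1, max_freq + 1):
        c, s = np.cos(k * ang), np.sin(k * ang)
        c, s = c - c.mean(), s - s.mean()
        basis = np.stack([c, s], axis=1)
        coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
        expl = float(((basis @ coef) ** 2).sum())
        best = max(best, expl / tot)
    return best


def task_fprime_template(
    model: V1Model,
    context: str,
    rng: np.random.Generator | int = 0,
    n_reps: int = 20,
    contrast: float = 2.0,
    swap_discriminanda: bool = False,
) -> np.ndarray:
    """Population sensitivity along a context's discrimination axis.

    Estimated as the finite difference of mean responses to noiseless
    gratings at the context's two discriminanda (the rotation carrying one
    into the other), divided by two.  The result is positive for neurons
    preferring the first discriminandum and negative for the second, sums to
    approximately zero, and flips sign when the discriminanda are swapped.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    rng = np.random.default_rng(rng)
    phi1, phi2 = CONTEXTS[context]
    if swap_discriminanda:
        phi1, phi2 = phi2, phi1
    means = []
    for phi in (phi1, phi2):
        img = contrast * model._grating(phi)
        images = np.tile(img, (n_reps, 1))
        cue = np.full(n_reps, context == "cardinal")
        resp = simulate_v1_session(
            model, n_reps, rng=rng, images=images, cue_is_cardinal=cue
        )
        means.append(resp.mean(axis=0))
    return (means[0] - means[1]) / 2.0
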