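"""Clusters-of-Samples observer models for Mode and Mean estimation.

Mode model: report the centroid C* of the heaviest cluster of one clustering
run; the overt response is y = b0 + b1*C* + Gaussian noise, so the trial
likelihood is a Monte-Carlo mixture of Gaussians over the ensemble.

Mean model: the same representation supports the Mean report through two
weight transformations — a power distortion w_k^alpha (probability
distortion) and a Gaussian-distance shunting term (lateral inhibition with
scale sigma_LI) — giving subjective weights theta_k and the point estimate
M* = sum_k c_k theta_k. Which representation was in use on a trial is
inferred from the observed Mode response (a posterior over the ensemble's
runs), reflecting a single representation shared by both tasks.

The subjective-weighting (SW) baseline applies the same lateral-inhibition
transformation directly to the 70 samples, with no clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .ddcrp import ClusterEnsemble, CoSRepresentation, sample_partition
from .stimgen import TrialStimulus

__all__ = [
    "ResponseModelParams",
    "CoSMeanParams",
    "LesionFlags",
    "mode_point",
    "mode_points",
    "mode_loglik",
    "set_posterior",
    "subjective_weights",
    "mean_point",
    "mean_points",
    "mean_loglik",
    "sw_weights",
    "sw_mean_point",
    "sw_mean_loglik",
    "simulate_responses",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ResponseModelParams:
    """Linear response transform y = beta0 + beta1*estimate + N(0, sigma^2)."""

    beta0: float
    beta1: float
    sigma: float

    def __post_init__(self) -> None:
        # sigma == 0 is allowed for noiseless simulation; likelihoods reject it
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class CoSMeanParams:
    """Mean-model parameters: power exponent, lateral-inhibition scale, response."""

    alpha_pow: float
    sigma_li: float
    response: ResponseModelParams

    def __post_init__(self) -> None:
        if self.alpha_pow <= 0 or self.sigma_li <= 0:
            raise ValueError("alpha_pow and sigma_li must be positive")


@dataclass(frozen=True)
class LesionFlags:
    use_power: bool = True
    use_lateral_inhibition: bool = True
    use_mode_prior: bool = True


def _norm_logpdf(y: float, mu: np.ndarray, sigma: float) -> np.ndarray:
    return -0.5 * ((y - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI


def mode_point(rep: CoSRepresentation, rng: np.random.Generator) -> float:
    """Centroid of the heaviest cluster; exact weight ties broken uniformly."""
    w = rep.weights
    best = np.flatnonzero(w == w.max())
    k = best[0] if best.size == 1 else rng.choice(best)
    return float(rep.centroids[k])


def mode_points(ensemble: ClusterEnsemble, rng: np.random.Generator | None = None) -> np.ndarray:
    """C* for every representation of an ensemble (vectorised tie-break).

    Ties in the maximal weight are broken uniformly at random by adding a
    sub-resolution jitter to the sizes (weights are multiples of 1/n, so the
    jitter can never reorder genuinely different weights).
    """
    if rng is None:
        rng = np.random.default_rng(ensemble.rng_seed + 1)
    key = ensemble.sizes + rng.uniform(0.0, 0.5, size=ensemble.sizes.shape)
    rep_of = np.repeat(np.arange(ensemble.R), np.diff(ensemble.rep_ptr))
    order = np.lexsort((key, rep_of))
    winners = order[ensemble.rep_ptr[1:] - 1]
    return ensemble.centroids[winners]


def mode_loglik(y_mode: float, cstar: np.ndarray | ClusterEnsemble, params: ResponseModelParams) -> float:
    """Log of the R-component Gaussian mixture likelihood of one Mode response."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive for likelihood evaluation")
    if isinstance(cstar, ClusterEnsemble):
        cstar = mode_points(cstar)
    mu = params.beta0 + params.beta1 * cstar
    return float(logsumexp(_norm_logpdf(y_mode, mu, params.sigma)) - np.log(cstar.size))


def set_posterior(y_mode: float, cstar: np.ndarray | ClusterEnsemble, sigma_mode: float) -> np.ndarray:
    """Posterior over ensemble runs given the observed Mode response.

    The response is compared to the raw C* of each run (no linear transform),
    as the likelihood of the representation-selection stage is defined.
    """
    if isinstance(cstar, ClusterEnsemble):
        cstar = mode_points(cstar)
    logw = -((y_mode - cstar) ** 2) / (2.0 * sigma_mode**2)
    logw -= logsumexp(logw)
    return np.exp(logw)


def subjective_weights(
    rep: CoSRepresentation, params: CoSMeanParams, lesions: LesionFlags = LesionFlags()
) -> np.ndarray:
    """Power-transformed, laterally-inhibited cluster weights (sum to 1)."""
    w, c = rep.weights, rep.centroids
    a = params.alpha_pow if lesions.use_power else 1.0
    num = w**a
    if lesions.use_lateral_inhibition:
        d2 = (c[None, :] - c[:, None]) ** 2
        num = num / (np.exp(-d2 / (2.0 * params.sigma_li**2)) @ w)
    return num / num.sum()


def mean_point(
    rep: CoSRepresentation, params: CoSMeanParams, lesions: LesionFlags = LesionFlags()
) -> float:
    """M* = sum_k c_k theta_k for one representation."""
    return float(rep.centroids @ subjective_weights(rep, params, lesions))


def _padded(ensemble: ClusterEnsemble) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(R, Kmax) weight/centroid arrays padded with zero weight."""
    kk = np.diff(ensemble.rep_ptr)
    kmax = int(kk.max())
    rep_of = np.repeat(np.arange(ensemble.R), kk)
    pos = np.arange(ensemble.weights.size) - ensemble.rep_ptr[rep_of]
    w = np.zeros((ensemble.R, kmax))
    c = np.zeros((ensemble.R, kmax))
    w[rep_of, pos] = ensemble.weights
    c[rep_of, pos] = ensemble.centroids
    return w, c, w > 0


def mean_points(
    ensemble: ClusterEnsemble, params: CoSMeanParams, lesions: LesionFlags = LesionFlags()
) -> np.ndarray:
    """M* for every representation of an ensemble (vectorised)."""
    w, c, mask = _padded(ensemble)
    a = params.alpha_pow if lesions.use_power else 1.0
    num = np.where(mask, w**a, 0.0)
    if lesions.use_lateral_inhibition:
        d2 = (c[:, :, None] - c[:, None, :]) ** 2
        inhib = np.einsum("rkj,rj->rk", np.exp(-d2 / (2.0 * params.sigma_li**2)), w)
        num = np.where(mask, num / inhib, 0.0)
    theta = num / num.sum(axis=1, keepdims=True)
    return np.einsum("rk,rk->r", theta, c)


def mean_loglik(
    y_mean: float,
    ensemble: ClusterEnsemble,
    params: CoSMeanParams,
    lesions: LesionFlags = LesionFlags(),
    mstar: np.ndarray | None = None,
) -> float:
    """Posterior-weighted Gaussian-mixture log likelihood of one Mean response.

    With the mode-derived prior lesioned off the mixture is uniform over runs.
    """
    if params.response.sigma <= 0:
        raise ValueError("sigma must be positive for likelihood evaluation")
    if mstar is None:
        mstar = mean_points(ensemble, params, lesions)
    r = params.response
    logpdf = _norm_logpdf(y_mean, r.beta0 + r.beta1 * mstar, r.sigma)
    if lesions.use_mode_prior:
        if ensemble.posterior_weights is None:
            raise ValueError("ensemble lacks posterior weights; set them or lesion the prior")
        with np.errstate(divide="ignore"):
            return float(logsumexp(logpdf + np.log(ensemble.posterior_weights)))
    return float(logsumexp(logpdf) - np.log(mstar.size))


def sw_weights(positions: np.ndarray, sigma_li: float) -> np.ndarray:
    """Per-sample subjective weights of the no-clustering (SW) model."""
    x = np.asarray(positions, dtype=float)
    d2 = (x[None, :] - x[:, None]) ** 2
    inv = 1.0 / np.exp(-d2 / (2.0 * sigma_li**2)).sum(axis=1)
    return inv / inv.sum()


def sw_mean_point(positions: np.ndarray, sigma_li: float) -> float:
    return float(np.asarray(positions, float) @ sw_weights(positions, sigma_li))


def sw_mean_loglik(
    y_mean: float, positions: np.ndarray, sigma_li: float, params: ResponseModelParams
) -> float:
    """Single-Gaussian log likelihood of a Mean response under the SW model."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive for likelihood evaluation")
    mu = params.beta0 + params.beta1 * sw_mean_point(positions, sigma_li)
    return float(_norm_logpdf(y_mean, np.asarray(mu), params.sigma))


def simulate_responses(
    stimuli: list[TrialStimulus],
    gamma: float,
    mode_params: ResponseModelParams,
    mean_params: CoSMeanParams,
    lesions: LesionFlags = LesionFlags(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one simulated subject's Mode and Mean responses.

    Per trial a single clustering run serves as the shared representation for
    both tasks: y_mode from its C*, y_mean from its M*, each linearly
    transformed and perturbed by the model's Gaussian response noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, st in enumerate(stimuli):
        _, rep = sample_partition(st.positions, gamma, rng)
        cstar = mode_point(rep, rng)
        mstar = mean_point(rep, mean_params, lesions)
        y_mode = mode_params.beta0 + mode_params.beta1 * cstar + rng.normal(0.0, mode_params.sigma)
        r = mean_params.response
        y_mean = r.beta0 + r.beta1 * mstar + rng.normal(0.0, r.sigma)
        rows.append(dict(trial=i, y_mode=y_mode, y_mean=y_mean, c_star=cstar, m_star=mstar))
    return pd.DataFrame(rows)
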