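"""Dirichlet-process mixture-model (DPMM) ideal observer.

The ideal observer assumes each sample x_i descends from a latent Gaussian
cluster: cluster means are drawn from a uniform base measure on [a, b] via a
Dirichlet process with concentration alpha, all clusters share one precision
tau ~ Gamma(alpha_tau, beta_tau) with a Gamma(1,1) hyperprior on beta_tau,
and a Gamma(alpha_c, 1) prior sits on alpha. Posterior inference uses a
Gibbs sampler with the auxiliary-component update for the non-conjugate base
(m = 3 auxiliary components), truncated-Gaussian conditionals for cluster
means, gamma conditionals for tau and beta_tau, and the beta-augmentation
update for alpha. The observer reports the posterior average of the mixture
mean and mixture mode (grid argmax of the mixture density) over retained
draws.

The per-sweep inner loop is JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .cos_models import ResponseModelParams, _norm_logpdf
from .stimgen import TrialStimulus

__all__ = [
    "DPMMConfig",
    "PosteriorDraws",
    "dpmm_mcmc",
    "mixture_stats",
    "io_estimates",
    "io_loglik",
    "concentration_update",
    "crp_cluster_count",
]


@dataclass(frozen=True)
class DPMMConfig:
    base_low: float = -20.0
    base_high: float = 20.0
    alpha_tau: float = 1.0
    alpha_c: float = 1.0
    chains: int = 4
    iters: int = 500
    burn_in: int = 250
    grid_step: float = 0.01
    aux_m: int = 3

    def __post_init__(self) -> None:
        if self.base_low >= self.base_high:
            raise ValueError("base interval is empty")
        if self.burn_in >= self.iters:
            raise ValueError("burn_in must be below iters")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC states summarised per draw, plus the average density."""

    per_draw_mean: np.ndarray
    per_draw_mode: np.ndarray
    per_draw_k: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    beta_tau: np.ndarray
    grid: np.ndarray
    mean_density: np.ndarray


@njit(cache=True)
def _chain(x, a, b, alpha_c, alpha_tau, aux_m, iters, burn_in, grid, seed):  # pragma: no cover
    np.random.seed(seed)
    n = x.size
    maxk = n + aux_m + 1
    mu = np.zeros(maxk)
    counts = np.zeros(maxk, dtype=np.int64)
    z = np.zeros(n, dtype=np.int64)
    # start from a single cluster at the sample mean
    k_act = 1
    mu[0] = x.mean()
    counts[0] = n
    tau = 1.0
    beta_tau = 1.0
    alpha = alpha_c
    n_keep = iters - burn_in
    means = np.empty(n_keep)
    modes = np.empty(n_keep)
    ks = np.empty(n_keep, dtype=np.int64)
    taus = np.empty(n_keep)
    alphas = np.empty(n_keep)
    beta_taus = np.empty(n_keep)
    dens_sum = np.zeros(grid.size)
    aux = np.empty(aux_m)
    logw = np.empty(maxk)

    for it in range(iters):
        # --- cluster assignments (auxiliary-component update) ---
        for i in range(n):
            c = z[i]
            counts[c] -= 1
            if counts[c] == 0:
                # the emptied cluster's mean becomes the first auxiliary one
                aux[0] = mu[c]
                for j in range(1, aux_m):
                    aux[j] = a + (b - a) * np.random.random()
                k_act -= 1
                if c != k_act:
                    mu[c] = mu[k_act]
                    counts[c] = counts[k_act]
                    for t in range(n):
                        if z[t] == k_act:
                            z[t] = c
            else:
                for j in range(aux_m):
                    aux[j] = a + (b - a) * np.random.random()
            half = 0.5 * tau
            for k in range(k_act):
                logw[k] = np.log(counts[k]) - half * (x[i] - mu[k]) ** 2
            for j in range(aux_m):
                logw[k_act + j] = np.log(alpha / aux_m) - half * (x[i] - aux[j]) ** 2
            m = logw[0]
            for k in range(1, k_act + aux_m):
                if logw[k] > m:
                    m = logw[k]
            tot = 0.0
            for k in range(k_act + aux_m):
                logw[k] = np.exp(logw[k] - m)
                tot += logw[k]
            u = np.random.random() * tot
            acc = 0.0
            pick = k_act + aux_m - 1
            for k in range(k_act + aux_m):
                acc += logw[k]
                if u <= acc:
                    pick = k
                    break
            if pick < k_act:
                z[i] = pick
                counts[pick] += 1
            else:
                mu[k_act] = aux[pick - k_act]
                counts[k_act] = 1
                z[i] = k_act
                k_act += 1

        # --- cluster means: truncated-Gaussian conditional on [a, b] ---
        for k in range(k_act):
            s = 0.0
            for i in range(n):
                if z[i] == k:
                    s += x[i]
            post_mean = s / counts[k]
            post_sd = 1.0 / np.sqrt(counts[k] * tau)
            draw = post_mean + post_sd * np.random.standard_normal()
            tries = 0
            while (draw < a or draw > b) and tries < 100:
                draw = post_mean + post_sd * np.random.standard_normal()
                tries += 1
            if draw < a:
                draw = a
            elif draw > b:
                draw = b
            mu[k] = draw

        # --- shared precision and its rate hyperparameter ---
        sse = 0.0
        for i in range(n):
            d = x[i] - mu[z[i]]
            sse += d * d
        tau = np.random.gamma(alpha_tau + 0.5 * n, 1.0 / (beta_tau + 0.5 * sse))
        beta_tau = np.random.gamma(1.0 + alpha_tau, 1.0 / (1.0 + tau))

        # --- concentration: beta augmentation for the Gamma(alpha_c, 1) prior ---
        eta = np.random.beta(alpha + 1.0, n)
        rate = 1.0 - np.log(eta)
        odds = (alpha_c + k_act - 1.0) / (n * rate)
        if np.random.random() < odds / (1.0 + odds):
            alpha = np.random.gamma(alpha_c + k_act, 1.0 / rate)
        else:
            alpha = np.random.gamma(alpha_c + k_act - 1.0, 1.0 / rate)

        if it >= burn_in:
            j = it - burn_in
            mean = 0.0
            for k in range(k_act):
                mean += counts[k] * mu[k]
            means[j] = mean / n
            norm = np.sqrt(tau / (2.0 * np.pi))
            best = -1.0
            best_g = grid[0]
            for g in range(grid.size):
                dens = 0.0
                for k in range(k_act):
                    dens += counts[k] * norm * np.exp(-0.5 * tau * (grid[g] - mu[k]) ** 2)
                dens /= n
                dens_sum[g] += dens
                if dens > best:  # strict: ties resolve to the lowest coordinate
                    best = dens
                    best_g = grid[g]
            modes[j] = best_g
            ks[j] = k_act
            taus[j] = tau
            alphas[j] = alpha
            beta_taus[j] = beta_tau
    return means, modes, ks, taus, alphas, beta_taus, dens_sum


def dpmm_mcmc(
    stimulus: TrialStimulus | np.ndarray, config: DPMMConfig, seed: int = 0
) -> PosteriorDraws:
    """Run the Gibbs sampler and summarise the retained posterior draws."""
    x = stimulus.positions if isinstance(stimulus, TrialStimulus) else np.asarray(stimulus, float)
    a, b = config.base_low, config.base_high
    if x.min() < a or x.max() > b:
        raise ValueError("samples outside the base support [a, b]")
    grid = np.arange(a, b + config.grid_step / 2, config.grid_step)
    seeds = np.random.SeedSequence(seed).generate_state(config.chains) % (2**31 - 1)
    parts = [
        _chain(
            x, a, b, config.alpha_c, config.alpha_tau, config.aux_m,
            config.iters, config.burn_in, grid, int(s),
        )
        for s in seeds
    ]
    cat = [np.concatenate([p[i] for p in parts]) for i in range(6)]
    n_draws = config.chains * (config.iters - config.burn_in)
    dens = sum(p[6] for p in parts) / n_draws
    return PosteriorDraws(cat[0], cat[1], cat[2], cat[3], cat[4], cat[5], grid, dens)


def mixture_stats(
    mus: np.ndarray, counts: np.ndarray, tau: float, grid: np.ndarray
) -> tuple[float, float]:
    """Mean and (grid-argmax) mode of a Gaussian mixture state.

    Ties at the argmax resolve to the lowest grid coordinate.
    """
    mus = np.asarray(mus, float)
    w = np.asarray(counts, float)
    w = w / w.sum()
    mean = float(w @ mus)
    dens = (w[:, None] * np.sqrt(tau / (2 * np.pi))
            * np.exp(-0.5 * tau * (grid[None, :] - mus[:, None]) ** 2)).sum(axis=0)
    return mean, float(grid[int(np.argmax(dens))])


def io_estimates(draws: PosteriorDraws) -> tuple[float, float]:
    """Posterior-averaged (Mean, Mode) point estimates."""
    return float(draws.per_draw_mean.mean()), float(draws.per_draw_mode.mean())


def io_loglik(y: float, estimate: float, params: ResponseModelParams) -> float:
    """Gaussian log likelihood of a response given the observer's estimate."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(_norm_logpdf(y, np.asarray(params.beta0 + params.beta1 * estimate), params.sigma))


def concentration_update(
    alpha: float, k: int, n: int, alpha_c: float, rng: np.random.Generator
) -> float:
    """One beta-augmentation update of the DP concentration (Gamma(alpha_c,1) prior)."""
    eta = rng.beta(alpha + 1.0, n)
    rate = 1.0 - np.log(eta)
    odds = (alpha_c + k - 1.0) / (n * rate)
    shape = alpha_c + k if rng.random() < odds / (1.0 + odds) else alpha_c + k - 1.0
    return float(rng.gamma(shape, 1.0 / rate))


def crp_cluster_count(alpha: float, n: int, rng: np.random.Generator) -> int:
    """Number of occupied tables after seating n customers in a CRP(alpha)."""
    k = 0
    for i in range(n):
        if rng.random() < alpha / (alpha + i):
            k += 1
    return k
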