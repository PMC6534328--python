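"""Maximum-likelihood fitting, AICc comparison, and group Bayesian model selection.

Per-subject fits minimise the negative log likelihood with bounded
Nelder-Mead simplex search from multiple space-filling starting points.
Stochastic parameters that the simplex cannot handle (the ddCRP distance
scale gamma; the DPMM concentration hyperparameter alpha_c) are grid
searched, optimising the remaining parameters at each grid value.

Models are compared per subject by AICc and at the group level by a
random-effects Bayesian model selection: variational Dirichlet updates over
model frequencies, exceedance probabilities by posterior sampling, and the
protected exceedance probability PXP = (1 - BOR) * EP + BOR / K, where the
Bayes omnibus risk BOR is the posterior probability that all models are
equally frequent in the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import qmc

__all__ = [
    "ModelFit",
    "GroupSelection",
    "aicc",
    "fit_mle",
    "grid_fit",
    "delta_aicc",
    "group_bms",
]

SIGMA_FLOOR = 1e-3  # cm; guards the likelihood against zero-noise degeneracy


@dataclass
class ModelFit:
    subject_id: int | str
    model_id: str
    task: str
    params: dict[str, float]
    neg_loglik: float
    n_trials: int
    k_params: int
    grid_value: float | None = None
    seed: int | None = None

    @property
    def aicc(self) -> float:
        return aicc(self.neg_loglik, self.k_params, self.n_trials)


@dataclass(frozen=True)
class GroupSelection:
    """Group-level random-effects model-selection summary."""

    alpha: np.ndarray          # Dirichlet posterior over model frequencies
    expected_freq: np.ndarray
    ep: np.ndarray             # exceedance probabilities
    bor: float                 # Bayes omnibus risk
    pxp: np.ndarray            # protected exceedance probabilities


def aicc(neg_loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the finite-sample correction."""
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    return 2.0 * neg_loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mle(
    nll: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int | None = None,
) -> tuple[np.ndarray, float]:
    """Bounded Nelder-Mead minimisation from space-filling starts.

    Returns the best (parameter vector, nll value) over all starts.
    Deterministic given the seed.
    """
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("bounds must be finite")
    starts = qmc.scale(qmc.LatinHypercube(d=len(bounds), seed=seed).random(n_starts), lo, hi)
    best_x, best_f = None, np.inf
    options = {"xatol": 1e-6, "fatol": 1e-8}
    if maxiter is not None:
        options["maxiter"] = maxiter
    for x0 in starts:
        res = minimize(nll, x0, method="Nelder-Mead", bounds=list(bounds), options=options)
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if best_x is None:
        raise RuntimeError("optimisation failed from every starting point")
    return best_x, best_f


def grid_fit(
    nll_factory: Callable[[float], Callable[[np.ndarray], float]],
    grid: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Grid search over one stochastic parameter, refitting the rest per value.

    ``nll_factory(g)`` must return the conditional nll over the remaining
    parameters. Returns (best grid value, best parameters, best nll).
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    best = (None, None, np.inf)
    for g in grid:
        x, f = fit_mle(nll_factory(g), bounds, n_starts=n_starts, seed=seed, maxiter=maxiter)
        if f < best[2]:
            best = (float(g), x, f)
    return best


def delta_aicc(fits: Sequence[ModelFit]) -> dict[str, float]:
    """Summed per-subject AICc differences from each subject's best model."""
    by_subject: dict = {}
    for f in fits:
        by_subject.setdefault(f.subject_id, []).append(f)
    models = sorted({f.model_id for f in fits})
    total = dict.fromkeys(models, 0.0)
    for subj, sf in by_subject.items():
        if sorted({f.model_id for f in sf}) != models:
            raise ValueError(f"subject {subj!r} is missing model fits")
        best = min(f.aicc for f in sf)
        for f in sf:
            total[f.model_id] += f.aicc - best
    return total


def _dirichlet_vb(log_evidence: np.ndarray, tol: float = 1e-8, max_iter: int = 500):
    """Variational posterior Dirichlet(alpha) and responsibilities u."""
    n, k = log_evidence.shape
    alpha0 = np.ones(k)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        logu = log_evidence + e_log_r
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    logu = log_evidence + e_log_r
    u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
    return alpha, u, e_log_r


def _free_energy(log_evidence, alpha, u, e_log_r) -> float:
    alpha0 = np.ones_like(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(u > 0, u * np.log(u), 0.0)
    f = float(np.sum(u * (log_evidence + e_log_r)) - np.sum(ent))
    f += float(gammaln(alpha0.sum()) - gammaln(alpha0).sum())
    f -= float(gammaln(alpha.sum()) - gammaln(alpha).sum())
    f += float(((alpha0 - alpha) * e_log_r).sum())
    return f


def group_bms(
    log_evidence: np.ndarray, n_samples: int = 100_000, seed: int = 0
) -> GroupSelection:
    """Random-effects Bayesian model selection over a subjects x models matrix.

    ``log_evidence`` holds per-subject model log evidences (here -AICc/2).
    """
    L = np.asarray(log_evidence, float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    if not np.isfinite(L).all():
        raise ValueError("log evidences must be finite")
    n, k = L.shape
    alpha, u, e_log_r = _dirichlet_vb(L)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=k) / n_samples
    f1 = _free_energy(L, alpha, u, e_log_r)
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(k)))  # all models equally frequent
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / k
    return GroupSelection(alpha, alpha / alpha.sum(), ep, bor, pxp)
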