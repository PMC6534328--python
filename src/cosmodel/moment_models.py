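"""Ground-truth and moment-regression baselines.

The response is modelled as a linear function of trial-level predictors
drawn from {true mode, true mean, true skewness} plus Gaussian noise:
Y = b0 + sum_j b_j Z_j + N(0, sigma^2). The ground-truth (GT) model uses the
task's own true statistic as its single predictor. Variance is never a
predictor because all stimuli are generated at a fixed sample SD.

These models predict a single Gaussian response density per trial, so they
cannot produce multimodal response distributions. Their maximum-likelihood
fit is ordinary least squares with the biased variance MLE, computed in
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_LOG2PI = np.log(2.0 * np.pi)

#: Predictor sets keyed by model id ("truth" resolves to the task statistic).
MOMENT_MODELS: dict[str, tuple[str, ...]] = {
    "GT": ("truth",),
    "MoMe": ("true_mode", "true_mean"),
    "MeSk": ("true_mean", "true_skewness"),
    "MoSk": ("true_mode", "true_skewness"),
    "MoMeSk": ("true_mode", "true_mean", "true_skewness"),
}

__all__ = ["MOMENT_MODELS", "MomentModelSpec", "moment_design", "moment_loglik", "fit_moment"]


@dataclass(frozen=True)
class MomentModelSpec:
    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in MOMENT_MODELS:
            raise ValueError(f"unknown moment model {self.model_id!r}")

    @property
    def q(self) -> int:
        return len(MOMENT_MODELS[self.model_id])

    @property
    def k_params(self) -> int:
        return self.q + 2  # intercept + slopes + sigma

    def predictors(self, task: str) -> tuple[str, ...]:
        if task not in ("mode", "mean"):
            raise ValueError(f"unknown task {task!r}")
        truth = "true_mode" if task == "mode" else "true_mean"
        return tuple(truth if p == "truth" else p for p in MOMENT_MODELS[self.model_id])


def moment_design(spec: MomentModelSpec, truth: pd.DataFrame, task: str) -> np.ndarray:
    """Predictor matrix (trials x q), columns in the spec's declared order."""
    cols = spec.predictors(task)
    return truth.loc[:, list(cols)].to_numpy(dtype=float)


def moment_loglik(y: np.ndarray, design: np.ndarray, beta: np.ndarray, sigma: float) -> float:
    """Summed Gaussian log likelihood of responses under Y = b0 + X b + noise."""
    y = np.asarray(y, float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if design.shape[0] != y.size or design.shape[1] != beta.size - 1:
        raise ValueError("dimension mismatch")
    resid = y - beta[0] - design @ beta[1:]
    return float(-0.5 * np.sum((resid / sigma) ** 2) - y.size * (np.log(sigma) + 0.5 * _LOG2PI))


def fit_moment(y: np.ndarray, design: np.ndarray, sigma_floor: float = 1e-3):
    """Closed-form MLE: OLS coefficients and the biased residual-SD estimate.

    Returns (beta with intercept first, sigma, maximised log likelihood).
    """
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(y.size), design])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma = max(float(np.sqrt(np.mean(resid**2))), sigma_floor)
    return beta, sigma, moment_loglik(y, design, beta, sigma)
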