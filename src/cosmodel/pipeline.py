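"""End-to-end orchestration: simulate cohorts, fit model sets, compare, summarise.

The canonical workflow mirrors the two-task design: per subject the Mode
responses are fitted first (the CoS Mode fit selects the ddCRP distance
scale gamma and yields a posterior over clustering runs per trial), and the
Mean responses are fitted second, reusing the Mode-derived representation
posterior. Model comparison uses AICc summed over subjects and group-level
random-effects Bayesian model selection (protected exceedance probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from sklearn.mixture import GaussianMixture

from . import cos_models as cm
from . import ddcrp, moment_models
from .ideal_observer import DPMMConfig, dpmm_mcmc, io_estimates
from .inference import SIGMA_FLOOR, ModelFit, delta_aicc, fit_mle, group_bms
from .stimgen import DesignSpec, TrialStimulus, condition_skewness

__all__ = [
    "FitSettings",
    "MODE_MODELS",
    "MEAN_MODELS",
    "LESION_MODELS",
    "simulate_cohort",
    "trial_ensembles",
    "fit_cohort_mode",
    "fit_cohort_mean",
    "lesion_battery",
    "error_summary",
    "icl_multimodality",
    "run_recovery",
]

MODE_MODELS = ("GT", "IO", "MoMe", "MeSk", "MoSk", "MoMeSk", "CoS")
MEAN_MODELS = ("GT", "IO", "MoMe", "MeSk", "MoSk", "MoMeSk", "CoS", "SW")
#: Mean-estimation lesion battery: full CoS, single/double transformation
#: lesions, the no-representation-sharing lesion, and the no-clustering SW.
LESION_MODELS = ("CoS", "CoS_noLI", "CoS_noPT", "CoS_noLIPT", "CoS_noPrior", "SW")

_LESION_FLAGS = {
    "CoS": cm.LesionFlags(),
    "CoS_noLI": cm.LesionFlags(use_lateral_inhibition=False),
    "CoS_noPT": cm.LesionFlags(use_power=False),
    "CoS_noLIPT": cm.LesionFlags(use_power=False, use_lateral_inhibition=False),
    "CoS_noPrior": cm.LesionFlags(use_mode_prior=False),
}


@dataclass
class FitSettings:
    """Problem sizes, grids and bounds shared by all fitting routines."""

    gamma_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.02, 2.0001, 0.02), 2))
    R: int = 1000
    alpha_c_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.1, 3.001, 0.1), 1))
    dpmm: DPMMConfig = field(default_factory=DPMMConfig)
    n_starts: int = 10
    maxiter: int | None = None
    seed: int = 0
    #: representations per trial used when evaluating Mean-task likelihoods
    #: (a subsample of the ensemble's R keeps the mixture evaluation cheap)
    R_mean: int = 1000
    #: iteration cap per start for the outer (alpha_pow, sigma_li) search
    outer_maxiter: int = 100
    beta0_bounds: tuple[float, float] = (-5.0, 5.0)
    beta1_bounds: tuple[float, float] = (0.0, 2.0)
    sigma_bounds: tuple[float, float] = (SIGMA_FLOOR, 10.0)
    alpha_pow_bounds: tuple[float, float] = (0.05, 3.0)
    sigma_li_bounds: tuple[float, float] = (0.1, 30.0)

    @classmethod
    def reduced(cls, seed: int = 0) -> "FitSettings":
        """Desk-scale settings for recovery studies (coarser grids, R=200)."""
        return cls(
            gamma_grid=np.round(np.arange(0.06, 2.0, 0.11), 2),
            R=200,
            alpha_c_grid=np.array([0.5, 1.5, 3.0]),
            dpmm=DPMMConfig(chains=2, iters=150, burn_in=75, grid_step=0.02),
            n_starts=3,
            maxiter=400,
            seed=seed,
            R_mean=100,
            outer_maxiter=50,
        )


# ---------------------------------------------------------------------------
# ensembles and caches


def trial_ensembles(
    stimuli: list[TrialStimulus], gamma: float, settings: FitSettings
) -> list[ddcrp.ClusterEnsemble]:
    """Per-trial clustering ensembles, deterministically keyed by trial.

    The per-trial RNG stream is shared across gamma values (common random
    numbers), so likelihood differences along the gamma grid reflect gamma
    itself rather than independent Monte-Carlo noise per grid point.
    """
    out = []
    for i, st in enumerate(stimuli):
        ss = np.random.SeedSequence([settings.seed, 3, i])
        out.append(ddcrp.build_ensemble(st, gamma, R=settings.R, seed=int(ss.generate_state(1)[0] % 2**31)))
    return out


def _cstar_matrix(ensembles: list[ddcrp.ClusterEnsemble]) -> np.ndarray:
    return np.stack([cm.mode_points(e) for e in ensembles])


def io_estimate_table(
    stimuli: list[TrialStimulus], alpha_c: float, settings: FitSettings
) -> np.ndarray:
    """(trials, 2) posterior-averaged (mean, mode) DPMM estimates at one alpha_c."""
    cfg = replace(settings.dpmm, alpha_c=float(alpha_c))
    rows = []
    for i, st in enumerate(stimuli):
        ss = np.random.SeedSequence([settings.seed, 7, int(round(alpha_c * 1e6)), i])
        draws = dpmm_mcmc(st, cfg, seed=int(ss.generate_state(1)[0] % 2**31))
        rows.append(io_estimates(draws))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# simulation


def simulate_cohort(
    stimuli: list[TrialStimulus],
    truth: pd.DataFrame,
    n_subjects: int = 16,
    generator: str = "cos",
    seed: int = 0,
    gamma: float = 0.5,
    return_params: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of subjects from one generating observer model.

    Generators: "cos" (ddCRP representation shared across tasks), "gt"
    (truth plus response noise in both tasks), "sw" (Mean from the
    subjective-weighting model, Mode from truth), "momesk" (linear in true
    mode, mean and skewness). Per-subject response parameters are jittered
    around identity (b0 ~ U(-0.5, 0.5), b1 ~ U(0.9, 1.1)).
    """
    master = np.random.SeedSequence([seed, 11])
    subject_seeds = master.spawn(n_subjects)
    frames = []
    param_rows = []
    for s, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        b0m, b0n = rng.uniform(-0.5, 0.5, 2)
        b1m, b1n = rng.uniform(0.9, 1.1, 2)
        sig_m = rng.uniform(1.0, 2.0)
        sig_n = rng.uniform(0.8, 1.5)
        sub_seed = int(rng.integers(2**31))
        param_rows.append(
            dict(subject=s, gamma=gamma, beta0_mode=b0m, beta1_mode=b1m, sigma_mode=sig_m,
                 beta0_mean=b0n, beta1_mean=b1n, sigma_mean=sig_n)
        )
        if generator == "cos":
            alpha_pow = rng.uniform(0.6, 0.8)
            sigma_li = rng.uniform(3.0, 5.0)
            param_rows[-1].update(alpha_pow=alpha_pow, sigma_li=sigma_li)
            mode_p = cm.ResponseModelParams(b0m, b1m, sig_m)
            mean_p = cm.CoSMeanParams(
                alpha_pow, sigma_li,
                cm.ResponseModelParams(b0n, b1n, sig_n),
            )
            df = cm.simulate_responses(stimuli, gamma, mode_p, mean_p, seed=sub_seed)
            df = df[["trial", "y_mode", "y_mean"]].copy()
        elif generator == "gt":
            r2 = np.random.default_rng(sub_seed)
            df = pd.DataFrame(
                dict(
                    trial=truth["trial"],
                    y_mode=b0m + b1m * truth["true_mode"] + r2.normal(0, sig_m, len(truth)),
                    y_mean=b0n + b1n * truth["true_mean"] + r2.normal(0, sig_n, len(truth)),
                )
            )
        elif generator == "sw":
            r2 = np.random.default_rng(sub_seed)
            sli = rng.uniform(3.0, 5.0)
            param_rows[-1].update(sigma_li=sli)
            est = np.array([cm.sw_mean_point(st.positions, sli) for st in stimuli])
            df = pd.DataFrame(
                dict(
                    trial=truth["trial"],
                    y_mode=b0m + b1m * truth["true_mode"] + r2.normal(0, sig_m, len(truth)),
                    y_mean=b0n + b1n * est + r2.normal(0, sig_n, len(truth)),
                )
            )
        elif generator == "momesk":
            r2 = np.random.default_rng(sub_seed)
            lin = (
                0.6 * truth["true_mode"] + 0.4 * truth["true_mean"] + 1.5 * truth["true_skewness"]
            )
            df = pd.DataFrame(
                dict(
                    trial=truth["trial"],
                    y_mode=b0m + b1m * lin + r2.normal(0, sig_m, len(truth)),
                    y_mean=b0n + b1n * lin + r2.normal(0, sig_n, len(truth)),
                )
            )
        else:
            raise ValueError(f"unknown generator {generator!r}")
        df.insert(0, "subject", s)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if return_params:
        return out, pd.DataFrame(param_rows)
    return out


# ---------------------------------------------------------------------------
# per-task fitting


def _mixture_nll_factory(y: np.ndarray, cstar: np.ndarray):
    """Vectorised negative log likelihood of Mode responses over an ensemble."""
    log_r = np.log(cstar.shape[1])

    def nll(p: np.ndarray) -> float:
        b0, b1, sigma = p
        if sigma < SIGMA_FLOOR:
            return np.inf
        z = (y[:, None] - b0 - b1 * cstar) / sigma
        row = -0.5 * z**2
        m = row.max(axis=1)
        ll = m + np.log(np.exp(row - m[:, None]).sum(axis=1)) - log_r
        ll -= np.log(sigma) + 0.5 * np.log(2 * np.pi)
        return -float(ll.sum())

    return nll


def _ols_fit(y: np.ndarray, cols: np.ndarray):
    """Closed-form Gaussian MLE of y on predictor columns (adds intercept)."""
    beta, sigma, ll = moment_models.fit_moment(y, cols)
    return beta, sigma, ll


def fit_cohort_mode(
    responses: pd.DataFrame,
    stimuli: list[TrialStimulus],
    truth: pd.DataFrame,
    settings: FitSettings,
    models: tuple[str, ...] = MODE_MODELS,
) -> tuple[list[ModelFit], dict]:
    """Fit all Mode-task models to every subject.

    Returns the fits and, for the CoS model, per-subject artifacts
    (best gamma, response parameters) needed by the Mean-task fits.
    """
    subjects = sorted(responses["subject"].unique())
    y_by_subj = {
        s: responses[responses["subject"] == s].sort_values("trial")["y_mode"].to_numpy()
        for s in subjects
    }
    n = len(stimuli)
    fits: list[ModelFit] = []
    artifacts: dict = {}

    bounds3 = [(-5.0, 5.0), (0.0, 2.0), settings.sigma_bounds]
    if "CoS" in models:
        best = {s: (np.inf, None, None) for s in subjects}
        for gamma in settings.gamma_grid:
            cstar = _cstar_matrix(trial_ensembles(stimuli, float(gamma), settings))
            for s in subjects:
                x, f = fit_mle(
                    _mixture_nll_factory(y_by_subj[s], cstar), bounds3,
                    n_starts=settings.n_starts, seed=settings.seed, maxiter=settings.maxiter,
                )
                if f < best[s][0]:
                    best[s] = (f, float(gamma), x)
        for s in subjects:
            f, gamma, x = best[s]
            params = dict(gamma=gamma, beta0=x[0], beta1=x[1], sigma_mode=x[2])
            fits.append(ModelFit(s, "CoS", "mode", params, f, n, 4, grid_value=gamma))
            artifacts[s] = params

    if "IO" in models:
        per_alpha = {
            float(a): io_estimate_table(stimuli, float(a), settings) for a in settings.alpha_c_grid
        }
        for s in subjects:
            best_f, best_a, best_beta, best_sig = np.inf, None, None, None
            for a, est in per_alpha.items():
                beta, sigma, ll = _ols_fit(y_by_subj[s], est[:, 1:2])  # mode column
                if -ll < best_f:
                    best_f, best_a, best_beta, best_sig = -ll, a, beta, sigma
            params = dict(alpha_c=best_a, beta0=best_beta[0], beta1=best_beta[1], sigma_mode=best_sig)
            fits.append(ModelFit(s, "IO", "mode", params, best_f, n, 4, grid_value=best_a))

    for mid in models:
        if mid in moment_models.MOMENT_MODELS:
            spec = moment_models.MomentModelSpec(mid)
            X = moment_models.moment_design(spec, truth, "mode")
            for s in subjects:
                beta, sigma, ll = _ols_fit(y_by_subj[s], X)
                params = {f"beta{j}": b for j, b in enumerate(beta)}
                params["sigma_mode"] = sigma
                fits.append(ModelFit(s, mid, "mode", params, -ll, n, spec.k_params))
    return fits, artifacts


def _subsample_reps(e: ddcrp.ClusterEnsemble, r: int) -> ddcrp.ClusterEnsemble:
    """View of an ensemble's first r representations."""
    end = int(e.rep_ptr[r])
    return ddcrp.ClusterEnsemble(
        e.positions, e.gamma, e.rng_seed, r, e.rep_ptr[: r + 1],
        e.centroids[:end], e.weights[:end], e.sizes[:end],
    )


def _stacked_padding(ensembles: list[ddcrp.ClusterEnsemble]):
    """Stack every trial's padded (R, Kmax) cluster arrays into (T*R, Kmax)."""
    ws, cs = [], []
    kmax = max(int(np.diff(e.rep_ptr).max()) for e in ensembles)
    for e in ensembles:
        w, c, _ = cm._padded(e)
        pad = kmax - w.shape[1]
        if pad:
            w = np.pad(w, ((0, 0), (0, pad)))
            c = np.pad(c, ((0, 0), (0, pad)))
        ws.append(w)
        cs.append(c)
    return np.concatenate(ws), np.concatenate(cs)


@njit(cache=True)
def _mstar_kernel(ptr, w, c, alpha_pow, inv2s2, use_pt, use_li, out):  # pragma: no cover
    """M* per representation over flat cluster arrays (ragged, via ptr)."""
    for r in range(ptr.size - 1):
        s, e = ptr[r], ptr[r + 1]
        tot = 0.0
        acc = 0.0
        for k in range(s, e):
            nk = w[k] ** alpha_pow if use_pt else w[k]
            if use_li:
                den = 0.0
                for j in range(s, e):
                    den += w[j] * np.exp(-((c[j] - c[k]) ** 2) * inv2s2)
                nk /= den
            tot += nk
            acc += nk * c[k]
        out[r] = acc / tot


class _CosMeanObjective:
    """Profile negative log likelihood of the (possibly lesioned) CoS Mean model.

    The transformation parameters (alpha_pow, sigma_li) alone determine the
    per-representation point estimates M*; for fixed M* the response
    parameters (beta0, beta1, sigma) are optimised by a cheap inner simplex
    search warm-started from the previous solution.
    """

    def __init__(
        self,
        y: np.ndarray,
        ensembles: list[ddcrp.ClusterEnsemble],
        log_post: np.ndarray,
        lesions: cm.LesionFlags,
        settings: "FitSettings",
    ) -> None:
        self.T, self.R = log_post.shape
        # flatten all trials' clusters into one ragged structure
        ptrs = [np.asarray(e.rep_ptr) for e in ensembles]
        offsets = np.cumsum([0] + [p[-1] for p in ptrs[:-1]])
        self.ptr = np.concatenate(
            [ptrs[0]] + [p[1:] + o for p, o in zip(ptrs[1:], offsets[1:])]
        ).astype(np.int64)
        self.w = np.concatenate([e.weights for e in ensembles])
        self.c = np.concatenate([e.centroids for e in ensembles])
        self.y = y
        self.log_post = log_post
        self.lesions = lesions
        self.settings = settings
        self._warm = None

    def mstar(self, alpha_pow: float, sigma_li: float) -> np.ndarray:
        out = np.empty(self.T * self.R)
        _mstar_kernel(
            self.ptr, self.w, self.c, float(alpha_pow), 0.5 / sigma_li**2,
            self.lesions.use_power and alpha_pow != 1.0, self.lesions.use_lateral_inhibition,
            out,
        )
        return out.reshape(self.T, self.R)

    def _response_nll(self, mstar: np.ndarray):
        y, log_post = self.y, self.log_post

        def nll(p: np.ndarray) -> float:
            b0, b1, sigma = p
            if sigma < SIGMA_FLOOR:
                return np.inf
            z = (y[:, None] - b0 - b1 * mstar) / sigma
            row = -0.5 * z**2 + log_post
            m = row.max(axis=1)
            ll = m + np.log(np.exp(row - m[:, None]).sum(axis=1))
            ll -= np.log(sigma) + 0.5 * np.log(2 * np.pi)
            return -float(ll.sum())

        return nll

    def profile(self, alpha_pow: float, sigma_li: float) -> tuple[float, np.ndarray]:
        """Best response-parameter nll at fixed transformation parameters."""
        ms = self.mstar(alpha_pow, sigma_li)
        nll = self._response_nll(ms)
        # warm start from the previous optimum; on the first call also from a
        # posterior-mean regression
        if self._warm is not None:
            x0s = [self._warm]
        else:
            mbar = np.einsum("tr,tr->t", np.exp(self.log_post), ms)
            beta, sigma, _ = _ols_fit(self.y, mbar[:, None])
            x0s = [np.array([beta[0], max(beta[1], 1e-3), max(sigma, 0.05)])]
        best_x, best_f = None, np.inf
        from scipy.optimize import minimize

        for x0 in x0s:
            res = minimize(
                nll, x0, method="Nelder-Mead",
                bounds=[self.settings.beta0_bounds, self.settings.beta1_bounds,
                        self.settings.sigma_bounds],
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 120},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
        self._warm = best_x
        return best_f, best_x


def _fit_mean_cos_subject(
    y_mean: np.ndarray,
    y_mode: np.ndarray,
    stimuli: list[TrialStimulus],
    settings: FitSettings,
    artifact: dict,
    lesions: cm.LesionFlags,
    ensembles: list[ddcrp.ClusterEnsemble] | None = None,
) -> tuple[dict, float, int, list[ddcrp.ClusterEnsemble]]:
    """Fit the (possibly lesioned) CoS Mean model for one subject.

    Outer bounded simplex search over the transformation parameters that the
    lesion leaves free; response parameters are profiled out per evaluation.
    """
    if ensembles is None:
        ensembles = trial_ensembles(stimuli, artifact["gamma"], settings)
    if settings.R_mean < ensembles[0].R:
        sub = [_subsample_reps(e, settings.R_mean) for e in ensembles]
    else:
        sub = ensembles
    R = sub[0].R
    if lesions.use_mode_prior:
        log_post = np.stack(
            [
                np.log(cm.set_posterior(y_mode[t], cm.mode_points(e), artifact["sigma_mode"])
                       + 1e-300)
                for t, e in enumerate(sub)
            ]
        )
    else:
        log_post = np.full((len(sub), R), -np.log(R))
    obj = _CosMeanObjective(y_mean, sub, log_post, lesions, settings)

    free: list[int] = []
    outer_bounds = []
    if lesions.use_power:
        free.append(0)
        outer_bounds.append(settings.alpha_pow_bounds)
    if lesions.use_lateral_inhibition:
        free.append(1)
        outer_bounds.append(settings.sigma_li_bounds)
    k = 3 + len(free)

    cache: dict[tuple, tuple] = {}

    def outer(q: np.ndarray) -> float:
        a = q[free.index(0)] if 0 in free else 1.0
        s = q[free.index(1)] if 1 in free else 1.0
        if (0 in free and not settings.alpha_pow_bounds[0] <= a <= settings.alpha_pow_bounds[1]) or (
            1 in free and not settings.sigma_li_bounds[0] <= s <= settings.sigma_li_bounds[1]
        ):
            return np.inf
        f, x = obj.profile(a, s)
        cache[tuple(np.round(q, 12))] = (f, x, a, s)
        return f

    if free:
        xq, f = fit_mle(
            outer, outer_bounds, n_starts=settings.n_starts, seed=settings.seed,
            maxiter=settings.outer_maxiter,
        )
        f, resp, a, s = cache[tuple(np.round(xq, 12))]
    else:
        f, resp = obj.profile(1.0, 1.0)
        a = s = 1.0
    params = dict(alpha_pow=a, sigma_li=s, beta0=resp[0], beta1=resp[1], sigma_mean=resp[2])
    return params, f, k, ensembles


def _fit_mean_sw_subject(y_mean: np.ndarray, stimuli: list[TrialStimulus], settings: FitSettings):
    """SW fit: profile out the linear-Gaussian part, line-search sigma_LI."""
    positions = np.stack([st.positions for st in stimuli])
    d2 = (positions[:, :, None] - positions[:, None, :]) ** 2

    def estimates(sigma_li: float) -> np.ndarray:
        inv = 1.0 / np.exp(-d2 / (2.0 * sigma_li**2)).sum(axis=2)
        theta = inv / inv.sum(axis=1, keepdims=True)
        return np.einsum("ti,ti->t", theta, positions)

    lo, hi = settings.sigma_li_bounds
    grid = np.geomspace(lo, hi, 40)
    best = (np.inf, None, None, None)
    for sli in grid:
        beta, sigma, ll = _ols_fit(y_mean, estimates(sli)[:, None])
        if -ll < best[0]:
            best = (-ll, sli, beta, sigma)
    f, sli, beta, sigma = best
    params = dict(sigma_li=float(sli), beta0=beta[0], beta1=beta[1], sigma_mean=sigma)
    return params, f


def fit_cohort_mean(
    responses: pd.DataFrame,
    stimuli: list[TrialStimulus],
    truth: pd.DataFrame,
    settings: FitSettings,
    cos_artifacts: dict,
    models: tuple[str, ...] = MEAN_MODELS,
) -> list[ModelFit]:
    """Fit all Mean-task models to every subject (CoS reuses the Mode artifacts)."""
    subjects = sorted(responses["subject"].unique())
    n = len(stimuli)
    fits: list[ModelFit] = []
    for s in subjects:
        sub = responses[responses["subject"] == s].sort_values("trial")
        y_mean = sub["y_mean"].to_numpy()
        y_mode = sub["y_mode"].to_numpy()
        ensembles = None
        for mid in models:
            if mid == "CoS":
                params, f, k, ensembles = _fit_mean_cos_subject(
                    y_mean, y_mode, stimuli, settings, cos_artifacts[s], cm.LesionFlags(),
                    ensembles,
                )
                fits.append(ModelFit(s, "CoS", "mean", params, f, n, k))
            elif mid == "SW":
                params, f = _fit_mean_sw_subject(y_mean, stimuli, settings)
                fits.append(ModelFit(s, "SW", "mean", params, f, n, 4))
            elif mid == "IO":
                raise ValueError(
                    "the IO Mean model reuses the Mode-task alpha_c; "
                    "fit it via run_recovery or fit_mean_with_io"
                )
            elif mid in moment_models.MOMENT_MODELS:
                spec = moment_models.MomentModelSpec(mid)
                X = moment_models.moment_design(spec, truth, "mean")
                beta, sigma, ll = _ols_fit(y_mean, X)
                params = {f"beta{j}": b for j, b in enumerate(beta)}
                params["sigma_mean"] = sigma
                fits.append(ModelFit(s, mid, "mean", params, -ll, n, spec.k_params))
            else:
                raise ValueError(f"unknown mean model {mid!r}")
    return fits


def lesion_battery(
    responses: pd.DataFrame,
    stimuli: list[TrialStimulus],
    settings: FitSettings,
    cos_artifacts: dict,
) -> tuple[list[ModelFit], dict]:
    """Fit the Mean-task lesion set and summarise (summed dAICc, PXP)."""
    subjects = sorted(responses["subject"].unique())
    n = len(stimuli)
    fits: list[ModelFit] = []
    for s in subjects:
        sub = responses[responses["subject"] == s].sort_values("trial")
        y_mean = sub["y_mean"].to_numpy()
        y_mode = sub["y_mode"].to_numpy()
        ensembles = None
        for mid in LESION_MODELS:
            if mid == "SW":
                params, f = _fit_mean_sw_subject(y_mean, stimuli, settings)
                fits.append(ModelFit(s, "SW", "mean", params, f, n, 4))
                continue
            params, f, k, ensembles = _fit_mean_cos_subject(
                y_mean, y_mode, stimuli, settings, cos_artifacts[s], _LESION_FLAGS[mid],
                ensembles,
            )
            fits.append(ModelFit(s, mid, "mean", params, f, n, k))
    summary = summarise_fits(fits)
    return fits, summary


def summarise_fits(fits: list[ModelFit], seed: int = 0) -> dict:
    """Summed dAICc and group-level PXP for a complete subjects x models set."""
    models = sorted({f.model_id for f in fits})
    subjects = sorted({f.subject_id for f in fits})
    sums = delta_aicc(fits)
    evid = np.zeros((len(subjects), len(models)))
    for f in fits:
        evid[subjects.index(f.subject_id), models.index(f.model_id)] = -0.5 * f.aicc
    sel = group_bms(evid, seed=seed)
    return dict(
        models=models,
        summed_daicc={m: sums[m] for m in models},
        pxp={m: float(p) for m, p in zip(models, sel.pxp)},
        ep={m: float(p) for m, p in zip(models, sel.ep)},
        bor=sel.bor,
    )


# ---------------------------------------------------------------------------
# behavioural summaries


def error_summary(
    responses: pd.DataFrame, truth: pd.DataFrame, design: DesignSpec
) -> pd.DataFrame:
    """Mean estimation errors per (task, shape, weight) cell.

    Errors are response minus the trial's true statistic, averaged within
    subject and then across subjects (SE across subjects). Weight conditions
    carry the global skewness of their generating mixture so rows can be
    ordered as in the behavioural error curves.
    """
    df = responses.merge(truth, on="trial")
    df["mode_error"] = df["y_mode"] - df["true_mode"]
    df["mean_error"] = df["y_mean"] - df["true_mean"]
    skew_by_weight = {
        c.weight_label: condition_skewness(c)
        for c in {st for st in design.trials}
    }
    rows = []
    for task in ("mode", "mean"):
        per_subj = (
            df.groupby(["shape", "weight", "subject"])[f"{task}_error"].mean().reset_index()
        )
        g = per_subj.groupby(["shape", "weight"])[f"{task}_error"]
        agg = g.agg(["mean", "sem", "count"]).reset_index()
        for _, r in agg.iterrows():
            rows.append(
                dict(
                    task=task,
                    shape=r["shape"],
                    weight=r["weight"],
                    global_skew=skew_by_weight[str(r["weight"])],
                    mean_error=r["mean"],
                    se=r["sem"],
                    n=int(r["count"]),
                )
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["task", "global_skew", "shape"]).reset_index(drop=True)


def icl_multimodality(
    points: np.ndarray, max_components: int = 3, n_init: int = 20, seed: int = 0
) -> dict:
    """Select the number of response clusters by the ICL criterion.

    Fits full-covariance Gaussian mixtures with 1..max_components components
    by multi-start EM and scores each by ICL = BIC + 2 * assignment entropy
    (lower is better). Returns the selected count and whether the selected
    ICL beats the single-component ICL (evidence of multimodality).
    """
    X = np.asarray(points, float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need at least 10 points (rows)")
    icls = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init, random_state=seed,
            reg_covar=1e-6, tol=1e-8,
        ).fit(X)
        resp = gm.predict_proba(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.sum(np.where(resp > 0, resp * np.log(resp), 0.0))
        icls[k] = float(gm.bic(X) + 2.0 * ent)
    k_sel = min(icls, key=icls.get)
    return dict(k_selected=k_sel, icl=icls, multimodal=icls[k_sel] < icls[1])


# ---------------------------------------------------------------------------
# recovery harness


def run_recovery(
    stimuli: list[TrialStimulus],
    truth: pd.DataFrame,
    settings: FitSettings,
    generator: str = "cos",
    n_subjects: int = 8,
    seed: int = 0,
    gamma: float = 0.5,
    mode_models: tuple[str, ...] = MODE_MODELS,
    mean_models: tuple[str, ...] = MEAN_MODELS,
) -> dict:
    """Simulate a cohort from one generator and fit/compare the model sets.

    Returns summed dAICc and PXP per task plus the per-subject CoS parameter
    estimates (for parameter-recovery scatter against the generating values).
    """
    responses, gen_params = simulate_cohort(
        stimuli, truth, n_subjects, generator, seed=seed, gamma=gamma, return_params=True
    )
    mode_fits, artifacts = fit_cohort_mode(responses, stimuli, truth, settings, mode_models)
    mean_fits = fit_mean_with_io(
        responses, stimuli, truth, settings, artifacts, mode_fits, mean_models
    )
    report = dict(
        generator=generator,
        n_subjects=n_subjects,
        mode=summarise_fits(mode_fits, seed=seed),
        mean=summarise_fits(mean_fits, seed=seed),
        cos_mode_params={f.subject_id: f.params for f in mode_fits if f.model_id == "CoS"},
        cos_mean_params={f.subject_id: f.params for f in mean_fits if f.model_id == "CoS"},
        generating_params=gen_params,
        responses=responses,
        mode_fits=mode_fits,
        mean_fits=mean_fits,
    )
    return report


def fit_mean_with_io(
    responses: pd.DataFrame,
    stimuli: list[TrialStimulus],
    truth: pd.DataFrame,
    settings: FitSettings,
    cos_artifacts: dict,
    mode_fits: list[ModelFit],
    models: tuple[str, ...],
) -> list[ModelFit]:
    """Mean-task fits; the IO model reuses each subject's Mode-task alpha_c."""
    non_io = tuple(m for m in models if m != "IO")
    fits = fit_cohort_mean(responses, stimuli, truth, settings, cos_artifacts, non_io)
    if "IO" not in models:
        return fits
    io_mode = {f.subject_id: f for f in mode_fits if f.model_id == "IO"}
    if not io_mode:
        raise ValueError("IO mean model requires IO mode fits")
    est_cache: dict[float, np.ndarray] = {}
    n = len(stimuli)
    for s in sorted(responses["subject"].unique()):
        a = float(io_mode[s].grid_value)
        if a not in est_cache:
            est_cache[a] = io_estimate_table(stimuli, a, settings)
        y_mean = responses[responses["subject"] == s].sort_values("trial")["y_mean"].to_numpy()
        beta, sigma, ll = _ols_fit(y_mean, est_cache[a][:, 0:1])  # mean column
        params = dict(alpha_c=a, beta0=beta[0], beta1=beta[1], sigma_mean=sigma)
        fits.append(ModelFit(s, "IO", "mean", params, -ll, n, 3))
    return fits
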