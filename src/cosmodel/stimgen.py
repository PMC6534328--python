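"""Stimulus generation for the Mode/Mean estimation experiments.

Each trial presents 70 one-dimensional samples drawn from a "beta mix": a
mixture of 3 or 4 beta-shaped components of equal width that adjoin each
other's ends. The component shape (negatively skewed, symmetric, positively
skewed — "local skewness") and the left-to-right component weights ("global
skewness") are crossed factorially. Samples are rescaled to a fixed standard
deviation and jittered around the screen centre.

This module also computes the per-trial "true" statistics the observer models
are scored against: the sample mean, the (population) skewness, and the mode
defined as the highest peak of a diffusion kernel density estimate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kde import diffusion_kde

__all__ = [
    "SHAPE_PARAMS",
    "BetaMixCondition",
    "DesignSpec",
    "TrialStimulus",
    "TrueStats",
    "build_design",
    "sample_trial",
    "generate_experiment",
    "true_stats",
    "condition_skewness",
    "write_stimuli_csv",
    "read_stimuli_csv",
]

#: Beta shape parameters per local-skewness condition (component SD is about
#: 0.19 of the component width in all three cases).
SHAPE_PARAMS: dict[str, tuple[float, float]] = {
    "LocalNeg": (3.1, 1.1),
    "LocalSym": (2.9, 2.9),
    "LocalPos": (1.1, 3.1),
}

WEIGHTS_3 = (0.2, 0.3, 0.5)
WEIGHTS_4 = (0.1, 0.2, 0.3, 0.4)
N_SAMPLES = 70

#: Per-experiment target sample SD (cm; degrees for S1).
TARGET_SD = {"E1": 7.27, "E2": 7.20, "E3": 7.55, "S1": 7.27 * 4.5}


@dataclass(frozen=True)
class BetaMixCondition:
    """One cell of the stimulus design: component count, shape, weights."""

    n_components: int
    shape_label: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape_label not in SHAPE_PARAMS:
            raise ValueError(f"unknown shape label {self.shape_label!r}")
        if self.n_components != len(self.weights):
            raise ValueError("weights length must match n_components")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        base = {3: WEIGHTS_3, 4: WEIGHTS_4}.get(self.n_components)
        if base is None or tuple(sorted(self.weights)) != base:
            raise ValueError("weights must permute the canonical weight set")

    @property
    def alpha_beta(self) -> tuple[float, float]:
        return SHAPE_PARAMS[self.shape_label]

    @property
    def weight_label(self) -> str:
        """Compact left-to-right weight code, e.g. (0.2,0.5,0.3) -> '253'."""
        return "".join(str(int(round(w * 10))) for w in self.weights)


@dataclass(frozen=True)
class DesignSpec:
    """A full experiment design: ordered trial conditions plus scaling."""

    experiment_id: str
    trials: tuple[BetaMixCondition, ...]
    target_sd: float
    position_range: tuple[float, float] = (-20.0, 20.0)
    mean_range: tuple[float, float] = (-3.8, 3.8)
    mini_blocks: tuple[tuple[int, tuple[int, ...]], ...] | None = None


@dataclass(frozen=True)
class TrialStimulus:
    """The 70 sample positions of one trial with their generating condition."""

    condition: BetaMixCondition
    positions: np.ndarray
    rng_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        if self.positions.shape != (N_SAMPLES,):
            raise ValueError(f"expected {N_SAMPLES} positions")


@dataclass(frozen=True)
class TrueStats:
    true_mean: float
    true_skewness: float
    true_mode: float
    kde_grid_step: float


def _weight_permutations(base: tuple[float, ...]) -> list[tuple[float, ...]]:
    return sorted(set(itertools.permutations(base)), reverse=True)


def _conditions(n_components: int) -> list[BetaMixCondition]:
    base = WEIGHTS_3 if n_components == 3 else WEIGHTS_4
    return [
        BetaMixCondition(n_components, shape, w)
        for shape in SHAPE_PARAMS
        for w in _weight_permutations(base)
    ]


def build_design(experiment_id: str, rng_seed: int) -> DesignSpec:
    """Enumerate and shuffle the trial list of one experiment.

    E1: 3 shapes x 6 weight permutations x 9 repeats = 162 trials (3-beta).
    E2: 3 shapes x 24 weight permutations x 2 repeats = 144 trials (4-beta).
    E3: 72 3-beta trials (3x6x4) and 72 4-beta trials (3x24x1) arranged in 12
    alternating mini-blocks of 10-14 trials.
    S1: the E1 design on an orientation range of [0, 180) degrees.
    """
    rng = np.random.default_rng(rng_seed)
    if experiment_id in ("E1", "S1"):
        trials = [c for c in _conditions(3) for _ in range(9)]
        rng.shuffle(trials)
        kw = {}
        if experiment_id == "S1":
            kw = dict(position_range=(0.0, 180.0), mean_range=(90.0 - 17.1, 90.0 + 17.1))
        return DesignSpec(experiment_id, tuple(trials), TARGET_SD[experiment_id], **kw)
    if experiment_id == "E2":
        trials = [c for c in _conditions(4) for _ in range(2)]
        rng.shuffle(trials)
        return DesignSpec("E2", tuple(trials), TARGET_SD["E2"])
    if experiment_id == "E3":
        t3 = [c for c in _conditions(3) for _ in range(4)]
        t4 = list(_conditions(4))
        rng.shuffle(t3)
        rng.shuffle(t4)
        sizes3 = _block_sizes(rng)
        sizes4 = _block_sizes(rng)
        first3 = bool(rng.integers(2))
        trials: list[BetaMixCondition] = []
        blocks: list[tuple[int, tuple[int, ...]]] = []
        i3 = i4 = 0
        for b in range(12):
            use3 = (b % 2 == 0) == first3
            if use3:
                size = sizes3[b // 2]
                chunk, i3 = t3[i3 : i3 + size], i3 + size
            else:
                size = sizes4[b // 2]
                chunk, i4 = t4[i4 : i4 + size], i4 + size
            blocks.append((b, tuple(range(len(trials), len(trials) + size))))
            trials.extend(chunk)
        return DesignSpec("E3", tuple(trials), TARGET_SD["E3"], mini_blocks=tuple(blocks))
    raise ValueError(f"unknown experiment id {experiment_id!r}")


def _block_sizes(rng: np.random.Generator, total: int = 72, k: int = 6) -> list[int]:
    """Random sizes in [10, 14] for k mini-blocks summing to `total`."""
    sizes = [total // k] * k
    for _ in range(40):
        i, j = rng.integers(k), rng.integers(k)
        if i != j and sizes[i] < 14 and sizes[j] > 10:
            sizes[i] += 1
            sizes[j] -= 1
    return sizes


def mixture_rvs(
    condition: BetaMixCondition,
    size: int,
    rng: np.random.Generator,
    stratified: bool = True,
) -> np.ndarray:
    """Raw draws from the end-joined beta mixture on [0, m] (unit-width parts).

    With ``stratified`` (the default) each component receives exactly
    ``size * weight`` samples — the trial counts every weight set implies are
    integers (e.g. 14/21/35 of 70) — with sample positions i.i.d. within
    components. With ``stratified=False`` component membership itself is
    i.i.d. categorical.
    """
    a, b = condition.alpha_beta
    if stratified:
        counts = np.round(np.asarray(condition.weights) * size).astype(int)
        if counts.sum() != size:
            raise ValueError("weights do not divide the sample count evenly")
        comp = rng.permutation(np.repeat(np.arange(condition.n_components), counts))
    else:
        comp = rng.choice(condition.n_components, size=size, p=condition.weights)
    return comp + rng.beta(a, b, size=size)


def sample_trial(
    condition: BetaMixCondition,
    design: DesignSpec,
    rng_seed: int,
    max_redraws: int = 100,
    stratified: bool = True,
) -> TrialStimulus:
    """Draw, rescale, and jitter one trial's 70 sample positions.

    Samples are drawn i.i.d. from the beta mix, linearly rescaled so the
    sample SD equals the design's target exactly, then shifted by a jitter
    drawn uniformly from the interval of shifts that keeps the sample mean
    within the design's mean range and every sample within the position
    range. If no feasible shift exists the samples are redrawn.
    """
    rng = np.random.default_rng(rng_seed)
    centre = 0.5 * (design.mean_range[0] + design.mean_range[1])
    half_mean = 0.5 * (design.mean_range[1] - design.mean_range[0])
    for _ in range(max_redraws):
        raw = mixture_rvs(condition, N_SAMPLES, rng, stratified=stratified)
        sd = raw.std(ddof=1)
        if sd == 0.0:
            continue
        x = (raw - raw.mean()) * (design.target_sd / sd)
        lo = max(-half_mean, design.position_range[0] - centre - x.min())
        hi = min(half_mean, design.position_range[1] - centre - x.max())
        if lo > hi:
            continue
        shift = centre + rng.uniform(lo, hi)
        return TrialStimulus(condition, x + shift, rng_seed)
    raise RuntimeError("degenerate draw: no feasible jitter after redraws")


def generate_experiment(design: DesignSpec, rng_seed: int) -> list[TrialStimulus]:
    """Generate the full list of trial stimuli for a design, one seed per trial."""
    children = np.random.SeedSequence(rng_seed).spawn(len(design.trials))
    return [
        sample_trial(cond, design, int(ss.generate_state(1)[0] % 2**31))
        for cond, ss in zip(design.trials, children)
    ]


def true_stats(stimulus: TrialStimulus, design: DesignSpec, n_grid: int = 4096) -> TrueStats:
    """True mean, skewness and (diffusion-KDE) mode of a trial's samples."""
    x = stimulus.positions
    grid, dens, _ = diffusion_kde(x, *design.position_range, n_grid=n_grid)
    return TrueStats(
        true_mean=float(x.mean()),
        true_skewness=float(stats.skew(x, bias=True)),
        true_mode=float(grid[int(np.argmax(dens))]),
        kde_grid_step=float(grid[1] - grid[0]),
    )


def true_stats_table(stimuli: list[TrialStimulus], design: DesignSpec) -> pd.DataFrame:
    """Per-trial true statistics plus condition labels as a DataFrame."""
    rows = []
    for i, st in enumerate(stimuli):
        ts = true_stats(st, design)
        rows.append(
            dict(
                trial=i,
                shape=st.condition.shape_label,
                weight=st.condition.weight_label,
                n_components=st.condition.n_components,
                true_mean=ts.true_mean,
                true_skewness=ts.true_skewness,
                true_mode=ts.true_mode,
            )
        )
    return pd.DataFrame(rows)


def condition_skewness(condition: BetaMixCondition) -> float:
    """Population skewness of the beta-mix distribution itself (not a sample).

    Used to order weight conditions by increasing global skewness.
    """
    a, b = condition.alpha_beta
    m1 = a / (a + b)
    v = a * b / ((a + b) ** 2 * (a + b + 1.0))
    s_beta = 2 * (b - a) * np.sqrt(a + b + 1) / ((a + b + 2) * np.sqrt(a * b))
    m3_beta = s_beta * v**1.5
    w = np.asarray(condition.weights)
    centres = np.arange(condition.n_components) + m1
    mean = np.sum(w * centres)
    d = centres - mean
    var = np.sum(w * (v + d**2))
    m3 = np.sum(w * (m3_beta + 3 * d * v + d**3))
    return float(m3 / var**1.5)


def write_stimuli_csv(
    stimuli: list[TrialStimulus], design: DesignSpec, csv_path: str, sidecar_path: str | None = None
) -> None:
    """Write stimuli as tidy CSV plus a JSON sidecar with condition metadata."""
    rows = [
        dict(
            experiment=design.experiment_id,
            trial=i,
            sample_index=j,
            position_cm=float(p),
        )
        for i, st in enumerate(stimuli)
        for j, p in enumerate(st.positions)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {
            "experiment": design.experiment_id,
            "target_sd": design.target_sd,
            "position_range": list(design.position_range),
            "mean_range": list(design.mean_range),
            "trials": [
                dict(
                    trial=i,
                    n_components=st.condition.n_components,
                    shape=st.condition.shape_label,
                    weights=list(st.condition.weights),
                    rng_seed=st.rng_seed,
                )
                for i, st in enumerate(stimuli)
            ],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_stimuli_csv(csv_path: str, sidecar_path: str) -> tuple[list[TrialStimulus], DesignSpec]:
    """Inverse of :func:`write_stimuli_csv`."""
    df = pd.read_csv(csv_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    conds = {
        t["trial"]: (
            BetaMixCondition(t["n_components"], t["shape"], tuple(t["weights"])),
            t["rng_seed"],
        )
        for t in meta["trials"]
    }
    stimuli = []
    for trial, grp in df.groupby("trial"):
        cond, seed = conds[int(trial)]
        pos = grp.sort_values("sample_index")["position_cm"].to_numpy()
        stimuli.append(TrialStimulus(cond, pos, seed))
    design = DesignSpec(
        meta["experiment"],
        tuple(c for c, _ in (conds[i] for i in sorted(conds))),
        meta["target_sd"],
        tuple(meta["position_range"]),
        tuple(meta["mean_range"]),
    )
    return stimuli, design
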