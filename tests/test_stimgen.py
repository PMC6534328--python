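"""Stimulus designs, trial sampling, and true-statistics computation."""

import numpy as np
import pytest
from scipy import stats

from cosmodel import stimgen
from cosmodel.stimgen import (
    SHAPE_PARAMS,
    BetaMixCondition,
    build_design,
    condition_skewness,
    mixture_rvs,
    sample_trial,
    true_stats,
)


@pytest.mark.parametrize(
    "exp,n_trials,sd",
    [("E1", 162, 7.27), ("E2", 144, 7.20), ("E3", 144, 7.55), ("S1", 162, 7.27 * 4.5)],
)
def test_design_sizes_and_target_sd(exp, n_trials, sd):
    d = build_design(exp, rng_seed=1)
    assert len(d.trials) == n_trials
    assert d.target_sd == pytest.approx(sd)


def test_e1_composition():
    d = build_design("E1", rng_seed=2)
    assert sum(t.n_components == 3 for t in d.trials) == 162
    labels = {(t.shape_label, t.weight_label) for t in d.trials}
    assert len(labels) == 18  # 3 shapes x 6 weight permutations


def test_e3_miniblocks_alternate_and_partition():
    d = build_design("E3", rng_seed=3)
    assert sum(t.n_components == 3 for t in d.trials) == 72
    assert sum(t.n_components == 4 for t in d.trials) == 72
    assert len(d.mini_blocks) == 12
    kinds = []
    covered = []
    for _, idx in d.mini_blocks:
        assert 10 <= len(idx) <= 14
        ks = {d.trials[i].n_components for i in idx}
        assert len(ks) == 1  # block is pure 3-beta or pure 4-beta
        kinds.append(ks.pop())
        covered.extend(idx)
    assert sorted(covered) == list(range(144))
    assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternating


def test_unknown_experiment_rejected():
    with pytest.raises(ValueError):
        build_design("E9", rng_seed=0)


def test_invalid_weight_sets_rejected():
    with pytest.raises(ValueError):
        BetaMixCondition(3, "LocalSym", (0.2, 0.2, 0.6))
    with pytest.raises(ValueError):
        BetaMixCondition(3, "BadShape", (0.2, 0.3, 0.5))


def test_component_sd_is_019_of_width():
    """All three beta shapes have SD ~0.19 of the unit component width."""
    sds = []
    for a, b in SHAPE_PARAMS.values():
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        sds.append(np.sqrt(var))
    assert all(round(s, 2) == 0.19 for s in sds)
    # near-equal component variances across shapes (within ~1% relative SD)
    assert max(sds) / min(sds) < 1.01


def test_trial_scaling_jitter_and_bounds(e1_design):
    for seed in range(5):
        st = sample_trial(e1_design.trials[seed], e1_design, rng_seed=seed)
        assert st.positions.std(ddof=1) == pytest.approx(e1_design.target_sd, abs=1e-9)
        assert st.positions.min() >= e1_design.position_range[0]
        assert st.positions.max() <= e1_design.position_range[1]
        lo, hi = e1_design.mean_range
        assert lo <= st.positions.mean() <= hi


def test_scaling_preserves_skewness(e1_design):
    """The affine rescale+jitter cannot change sample skewness."""
    cond = e1_design.trials[0]
    rng = np.random.default_rng(99)
    raw = mixture_rvs(cond, 70, rng)
    st = sample_trial(cond, e1_design, rng_seed=99)
    assert stats.skew(st.positions, bias=True) == pytest.approx(
        stats.skew(raw, bias=True), abs=1e-9
    )


def test_component_counts_exact_by_default(rng):
    cond = BetaMixCondition(3, "LocalSym", (0.2, 0.3, 0.5))
    x = mixture_rvs(cond, 70, rng)
    counts = np.bincount(np.floor(x).astype(int), minlength=3)
    assert list(counts) == [14, 21, 35]


def test_iid_component_counts_converge_to_weights(rng):
    cond = BetaMixCondition(3, "LocalSym", (0.2, 0.3, 0.5))
    x = mixture_rvs(cond, 70 * 200, rng, stratified=False)
    freq = np.bincount(np.floor(x).astype(int), minlength=3) / (70 * 200)
    # binomial sampling error at n = 14000 is ~0.004 per component
    assert np.allclose(freq, (0.2, 0.3, 0.5), atol=0.015)


def test_true_stats_basics(e1_design):
    sym = np.concatenate([np.linspace(-8, -2, 35), np.linspace(2, 8, 35)])
    st = stimgen.TrialStimulus(e1_design.trials[0], sym, 0)
    ts = true_stats(st, e1_design)
    assert ts.true_mean == pytest.approx(0.0, abs=1e-12)
    assert ts.true_skewness == pytest.approx(0.0, abs=1e-12)


def test_true_mode_finds_majority_peak(e1_design, rng):
    pos = np.concatenate([rng.normal(-5, 1, 60), rng.normal(5, 1, 10)])
    st = stimgen.TrialStimulus(e1_design.trials[0], pos, 0)
    ts = true_stats(st, e1_design)
    assert abs(ts.true_mode - (-5)) < 0.5


def test_condition_skewness_orders_weight_conditions():
    neg = BetaMixCondition(3, "LocalSym", (0.2, 0.3, 0.5))
    pos = BetaMixCondition(3, "LocalSym", (0.5, 0.3, 0.2))
    assert condition_skewness(neg) < 0 < condition_skewness(pos)
    assert condition_skewness(neg) == pytest.approx(-condition_skewness(pos), abs=1e-12)


def test_csv_round_trip(tmp_path, e1_design):
    stimuli = [
        sample_trial(c, e1_design, rng_seed=i) for i, c in enumerate(e1_design.trials[:4])
    ]
    csv, sidecar = tmp_path / "stim.csv", tmp_path / "stim.json"
    stimgen.write_stimuli_csv(stimuli, e1_design, str(csv), str(sidecar))
    loaded, design = stimgen.read_stimuli_csv(str(csv), str(sidecar))
    assert design.target_sd == e1_design.target_sd
    for a, b in zip(stimuli, loaded):
        assert np.allclose(a.positions, b.positions)
        assert a.condition == b.condition
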