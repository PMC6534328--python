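"""ddCRP clustering: join matrix, sampling, exact enumeration oracle, histograms."""

import itertools

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from cosmodel import ddcrp


def _canonical(labels):
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, []).append(i)
    return tuple(sorted(tuple(g) for g in groups.values()))


def _sampled_distribution(positions, gamma, n_draws, seed):
    """Monte-Carlo distribution over set-partitions (vectorised sampler)."""
    p = ddcrp.join_probabilities(positions, gamma)
    cum = p.cumsum(axis=1)
    rng = np.random.default_rng(seed)
    n = len(positions)
    out = {}
    for start in range(0, n_draws, 20000):
        b = min(20000, n_draws - start)
        u = rng.random((b, n, 1))
        targets = (cum[None, :, :] < u).sum(axis=2)
        labels = ddcrp._labels_from_targets(targets)
        for row in labels:
            key = _canonical(row)
            out[key] = out.get(key, 0) + 1
    return {k: v / n_draws for k, v in out.items()}


def test_join_rows_are_stochastic_with_zero_diagonal(rng):
    x = rng.uniform(-10, 10, 12)
    p = ddcrp.join_probabilities(x, 0.7)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diag(p) == 0)


def test_equidistant_neighbours_share_probability():
    p = ddcrp.join_probabilities(np.array([0.0, 1.0, -1.0]), 2.0)
    assert p[0, 1] == pytest.approx(0.5, abs=1e-12)
    assert p[0, 2] == pytest.approx(0.5, abs=1e-12)


def test_join_log_ratio_follows_squared_distance():
    """log P(0 joins 1) - log P(0 joins 10) = (100 - 1)/gamma."""
    lp = ddcrp.join_log_probabilities(np.array([0.0, 1.0, 10.0]), 1.0)
    assert lp[0, 1] - lp[0, 2] == pytest.approx(99.0, abs=1e-9)


def test_single_sample_and_bad_gamma_rejected():
    with pytest.raises(ValueError):
        ddcrp.join_probabilities(np.array([1.0]), 1.0)
    with pytest.raises(ValueError):
        ddcrp.join_probabilities(np.array([1.0, 2.0]), 0.0)


def test_two_samples_always_one_cluster(rng):
    x = np.array([-3.0, 5.0])
    _, rep = ddcrp.sample_partition(x, 1.0, rng)
    assert rep.K == 1
    assert rep.weights[0] == 1.0
    assert rep.centroids[0] == pytest.approx(1.0)


def test_no_singletons_ever(rng):
    x = rng.uniform(-10, 10, 15)
    for _ in range(50):
        _, rep = ddcrp.sample_partition(x, 0.5, rng)
        assert rep.sizes.min() >= 2


def test_far_pairs_split_with_near_certainty():
    """Two tight, distant pairs: the paired partition has mass > 0.999."""
    x = np.array([0.0, 0.1, 100.0, 100.1])
    dist = ddcrp.enumerate_partitions(x, 0.01)
    assert dist[((0, 1), (2, 3))] > 0.999


def test_enumeration_is_a_probability_distribution(rng):
    x = rng.uniform(-5, 5, 5)
    dist = ddcrp.enumerate_partitions(x, 1.0)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-10)


def test_three_samples_always_fully_connected():
    """Any self-join-free join graph on 3 nodes is connected."""
    dist = ddcrp.enumerate_partitions(np.array([0.0, 1.0, 2.5]), 1.0)
    assert dist == {((0, 1, 2),): pytest.approx(1.0, abs=1e-12)}


def test_oracle_size_limit():
    with pytest.raises(ValueError):
        ddcrp.enumerate_partitions(np.zeros(9), 1.0)


def test_sampler_matches_enumeration_small_n(rng):
    x = rng.uniform(0, 3, 6)
    exact = ddcrp.enumerate_partitions(x, 1.0)
    mc = _sampled_distribution(x, 1.0, 100_000, seed=5)
    keys = set(exact) | set(mc)
    tv = 0.5 * sum(abs(exact.get(k, 0.0) - mc.get(k, 0.0)) for k in keys)
    assert tv < 0.01


def test_large_gamma_limit_is_uniform():
    x = np.array([-15.0, -3.0, 0.0, 7.0, 15.0])
    p = ddcrp.join_probabilities(x, 1e12)
    off = p[~np.eye(5, dtype=bool)]
    assert np.max(np.abs(off - 0.25)) < 1e-6


def test_small_gamma_limit_joins_nearest_neighbour():
    x = np.array([0.0, 1.0, 3.0, 6.0])
    p = ddcrp.join_probabilities(x, 1e-3)
    for j in range(4):
        others = [l for l in range(4) if l != j]
        nearest = min(others, key=lambda l: abs(x[j] - x[l]))
        assert p[j, nearest] > 1 - 1e-9


def test_permutation_equivariance(rng):
    """Relabelling samples leaves the set-partition distribution unchanged."""
    x = rng.uniform(-4, 4, 5)
    perm = rng.permutation(5)
    base = ddcrp.enumerate_partitions(x, 0.8)
    permuted = ddcrp.enumerate_partitions(x[perm], 0.8)
    inv = np.argsort(perm)
    remapped = {}
    for key, prob in permuted.items():
        new = tuple(sorted(tuple(sorted(perm[i] for i in grp)) for grp in key))
        remapped[new] = remapped.get(new, 0.0) + prob
    for key in set(base) | set(remapped):
        assert base.get(key, 0.0) == pytest.approx(remapped.get(key, 0.0), abs=1e-12)


def test_ensemble_seeding_contract(e1_trial):
    a = ddcrp.build_ensemble(e1_trial, 0.5, R=50, seed=9)
    b = ddcrp.build_ensemble(e1_trial, 0.5, R=50, seed=9)
    assert np.array_equal(a.rep_ptr, b.rep_ptr)
    assert np.array_equal(a.centroids, b.centroids)
    assert np.array_equal(a.sizes, b.sizes)


def test_ensemble_r1_equals_single_draw(e1_trial):
    ens = ddcrp.build_ensemble(e1_trial, 0.5, R=1, seed=4)
    assert ens.R == 1
    rep = ens.rep(0)
    assert rep.sizes.sum() == 70
    assert rep.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_centroid_weight_sum_conserves_sample_mean(e1_trial):
    """The CoS summary is exactly mean-preserving for every run."""
    ens = ddcrp.build_ensemble(e1_trial, 0.7, R=200, seed=2)
    mean = e1_trial.positions.mean()
    for j in range(ens.R):
        rep = ens.rep(j)
        assert rep.centroids @ rep.weights == pytest.approx(mean, abs=1e-10)


def test_size_histogram_trivial_cases(e1_trial):
    ens = ddcrp.build_ensemble(e1_trial, 0.5, R=30, seed=1)
    hist = ddcrp.cluster_size_histogram([ens])
    assert hist.sum() == pytest.approx(1.0, abs=1e-9)
    # a two-cluster representation of sizes (35, 35) puts all mass at 35
    e = ddcrp.ClusterEnsemble(
        e1_trial.positions, 1.0, 0, 2,
        np.array([0, 2, 4]), np.zeros(4), np.full(4, 0.5), np.full(4, 35),
    )
    h = ddcrp.cluster_size_histogram([e])
    assert h[34] == pytest.approx(1.0)
    assert h.sum() == pytest.approx(1.0)
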