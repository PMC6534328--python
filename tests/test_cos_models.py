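"""CoS and subjective-weighting observer models: point estimates and likelihoods."""

import numpy as np
import pytest
from scipy.stats import norm

from cosmodel import cos_models as cm
from cosmodel import ddcrp
from cosmodel.ddcrp import CoSRepresentation


def _rep(weights, centroids):
    w = np.asarray(weights, float)
    return CoSRepresentation(np.asarray(centroids, float), w, np.round(w * 70).astype(int))


def test_mode_point_is_heaviest_centroid(rng):
    assert cm.mode_point(_rep([1.0], [3.3]), rng) == 3.3
    assert cm.mode_point(_rep([0.2, 0.3, 0.5], [-5, 0, 5]), rng) == 5


def test_mode_point_ties_break_uniformly(rng):
    rep = _rep([0.5, 0.5], [-1.0, 1.0])
    picks = np.array([cm.mode_point(rep, rng) for _ in range(100_000)])
    assert np.mean(picks == 1.0) == pytest.approx(0.5, abs=0.01)


def test_mode_loglik_single_and_degenerate_mixture():
    p = cm.ResponseModelParams(0.5, 1.2, 0.8)
    single = cm.mode_loglik(1.0, np.array([2.0]), p)
    assert single == pytest.approx(norm.logpdf(1.0, 0.5 + 1.2 * 2.0, 0.8), abs=1e-12)
    same = cm.mode_loglik(1.0, np.array([2.0, 2.0, 2.0]), p)
    assert same == pytest.approx(single, abs=1e-12)


def test_mode_loglik_symmetric_two_point_mixture():
    """C* = {0, 2}, identity transform, sigma 1, y = 1: both terms equal phi(1)."""
    p = cm.ResponseModelParams(0.0, 1.0, 1.0)
    ll = cm.mode_loglik(1.0, np.array([0.0, 2.0]), p)
    assert ll == pytest.approx(norm.logpdf(1.0), abs=1e-12)


def test_mode_loglik_requires_positive_sigma():
    with pytest.raises(ValueError):
        cm.mode_loglik(0.0, np.array([0.0]), cm.ResponseModelParams(0, 1, 0.0))


def test_set_posterior_normalises_and_limits():
    cstar = np.array([0.0, 1.0, 4.0])
    post = cm.set_posterior(1.1, cstar, 2.0)
    assert post.sum() == pytest.approx(1.0, abs=1e-12)
    tight = cm.set_posterior(1.1, cstar, 1e-4)
    assert tight[1] == pytest.approx(1.0, abs=1e-12)
    flat = cm.set_posterior(0.3, np.full(10, 2.0), 1.0)
    assert np.allclose(flat, 0.1, atol=1e-12)


def test_subjective_weights_reduce_to_w_in_limits():
    rep = _rep([0.2, 0.3, 0.5], [-5.0, 0.0, 5.0])
    p = cm.CoSMeanParams(1.0, 1e9, cm.ResponseModelParams(0, 1, 1))
    assert np.allclose(cm.subjective_weights(rep, p), rep.weights, atol=1e-10)
    lesioned = cm.LesionFlags(use_power=False, use_lateral_inhibition=False)
    p2 = cm.CoSMeanParams(0.3, 0.5, cm.ResponseModelParams(0, 1, 1))
    assert np.allclose(cm.subjective_weights(rep, p2, lesioned), rep.weights, atol=1e-15)


def test_subjective_weights_symmetric_pair():
    rep = _rep([0.5, 0.5], [-1.0, 1.0])
    p = cm.CoSMeanParams(1.0, 1.0, cm.ResponseModelParams(0, 1, 1))
    assert np.allclose(cm.subjective_weights(rep, p), [0.5, 0.5], atol=1e-12)


def test_mean_point_hand_oracle_power_only():
    """theta_k = w_k^0.5 / sum w^0.5 with LI off; M* checked by hand arithmetic."""
    rep = _rep([0.2, 0.3, 0.5], [-5.0, 0.0, 5.0])
    p = cm.CoSMeanParams(0.5, 1.0, cm.ResponseModelParams(0, 1, 1))
    les = cm.LesionFlags(use_lateral_inhibition=False)
    th = np.sqrt([0.2, 0.3, 0.5])
    th /= th.sum()
    expect = th @ np.array([-5.0, 0.0, 5.0])
    assert cm.mean_point(rep, p, les) == pytest.approx(expect, abs=1e-12)


def test_mean_point_faithful_weights_reproduce_sample_mean(e1_trial, rng):
    """With theta = w the Mean report equals the trial's sample mean exactly."""
    _, rep = ddcrp.sample_partition(e1_trial.positions, 0.5, rng)
    p = cm.CoSMeanParams(1.0, 1.0, cm.ResponseModelParams(0, 1, 1))
    les = cm.LesionFlags(use_power=False, use_lateral_inhibition=False)
    assert cm.mean_point(rep, p, les) == pytest.approx(e1_trial.positions.mean(), abs=1e-10)


def test_mean_points_matches_scalar_path(e1_trial):
    ens = ddcrp.build_ensemble(e1_trial, 0.8, R=20, seed=3)
    p = cm.CoSMeanParams(0.7, 2.0, cm.ResponseModelParams(0, 1, 1))
    vec = cm.mean_points(ens, p)
    scalar = np.array([cm.mean_point(ens.rep(j), p) for j in range(ens.R)])
    assert np.allclose(vec, scalar, atol=1e-10)


def test_mean_loglik_two_rep_hand_mixture(e1_trial):
    ens = ddcrp.build_ensemble(e1_trial, 0.8, R=2, seed=3)
    p = cm.CoSMeanParams(0.7, 2.0, cm.ResponseModelParams(0.1, 0.9, 1.3))
    ens.posterior_weights = np.array([0.75, 0.25])
    mstar = cm.mean_points(ens, p)
    y = 1.7
    expect = np.log(
        0.75 * norm.pdf(y, 0.1 + 0.9 * mstar[0], 1.3)
        + 0.25 * norm.pdf(y, 0.1 + 0.9 * mstar[1], 1.3)
    )
    assert cm.mean_loglik(y, ens, p) == pytest.approx(expect, abs=1e-10)


def test_mean_loglik_degenerate_posterior(e1_trial):
    ens = ddcrp.build_ensemble(e1_trial, 0.8, R=3, seed=3)
    p = cm.CoSMeanParams(0.7, 2.0, cm.ResponseModelParams(0.0, 1.0, 1.0))
    ens.posterior_weights = np.array([0.0, 1.0, 0.0])
    mstar = cm.mean_points(ens, p)
    assert cm.mean_loglik(0.5, ens, p) == pytest.approx(
        norm.logpdf(0.5, mstar[1], 1.0), abs=1e-10
    )


def test_mean_loglik_without_prior_is_uniform_mixture(e1_trial):
    ens = ddcrp.build_ensemble(e1_trial, 0.8, R=4, seed=3)
    p = cm.CoSMeanParams(0.7, 2.0, cm.ResponseModelParams(0.0, 1.0, 1.0))
    mstar = cm.mean_points(ens, p)
    les = cm.LesionFlags(use_mode_prior=False)
    expect = np.log(np.mean(norm.pdf(0.2, mstar, 1.0)))
    assert cm.mean_loglik(0.2, ens, p, les) == pytest.approx(expect, abs=1e-10)


def test_sw_two_samples_and_small_sigma_limit():
    x = np.array([-2.0, 4.0])
    assert np.allclose(cm.sw_weights(x, 3.0), [0.5, 0.5])
    assert cm.sw_mean_point(x, 3.0) == pytest.approx(1.0)
    many = np.array([0.0, 1.0, 3.0, 7.0, 9.5])
    # sigma_LI -> 0: only the self term survives, weights become uniform
    assert cm.sw_mean_point(many, 1e-4) == pytest.approx(many.mean(), abs=1e-12)


def test_sw_overestimates_mean_of_positive_skew():
    """Sparse right tail is overweighted: estimate exceeds the sample mean."""
    x = np.array([0.0, 1.0, 10.0])
    assert cm.sw_mean_point(x, 2.0) > x.mean()


def test_simulation_is_seeded_and_mean_faithful_when_unlesioned_weights(e1_trial):
    mode_p = cm.ResponseModelParams(0.0, 1.0, 0.0)
    mean_p = cm.CoSMeanParams(1.0, 1.0, cm.ResponseModelParams(0.0, 1.0, 0.0))
    les = cm.LesionFlags(use_power=False, use_lateral_inhibition=False)
    df1 = cm.simulate_responses([e1_trial] * 5, 0.5, mode_p, mean_p, les, seed=11)
    df2 = cm.simulate_responses([e1_trial] * 5, 0.5, mode_p, mean_p, les, seed=11)
    assert df1.equals(df2)
    # noiseless + faithful weights: the Mean report is the sample mean exactly
    assert np.allclose(df1["y_mean"], e1_trial.positions.mean(), atol=1e-10)
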