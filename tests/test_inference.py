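"""Fitting, AICc and group-level Bayesian model selection."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from cosmodel.inference import ModelFit, aicc, delta_aicc, fit_mle, grid_fit, group_bms


def test_aicc_formula_and_limits():
    # direct arithmetic: 2*100 + 2*4 + 2*4*5/157
    assert aicc(100.0, 4, 162) == pytest.approx(208 + 40 / 157, abs=1e-12)
    assert aicc(100.0, 4, 10**9) == pytest.approx(208.0, abs=1e-6)
    assert aicc(100.0, 4, 162) > 208.0  # correction is strictly positive
    with pytest.raises(ValueError):
        aicc(10.0, 4, 5)


def _gaussian_nll(y, x):
    def nll(p):
        b0, b1, sigma = p
        if sigma <= 0:
            return np.inf
        r = y - b0 - b1 * x
        return 0.5 * np.sum((r / sigma) ** 2) + len(y) * (
            np.log(sigma) + 0.5 * np.log(2 * np.pi)
        )

    return nll


def test_fit_mle_recovers_linear_gaussian_against_ols():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 5, 162)
    y = 2.0 + 1.0 * x + rng.normal(0, 1, 162)
    best, f = fit_mle(_gaussian_nll(y, x), [(-5, 5), (0, 2), (1e-3, 10)], seed=0)
    ref = sm.OLS(y, sm.add_constant(x)).fit()
    se = ref.bse
    assert abs(best[0] - 2.0) < 3 * se[0] + 1e-3
    assert abs(best[1] - 1.0) < 3 * se[1] + 1e-3
    assert np.allclose(best[:2], ref.params, atol=1e-3)
    assert f == pytest.approx(-ref.llf, abs=1e-3)


def test_fit_mle_deterministic_and_bounded():
    rng = np.random.default_rng(4)
    y = rng.normal(1, 0.5, 50)
    nll = _gaussian_nll(y, np.zeros(50))
    a = fit_mle(nll, [(-5, 5), (0, 2), (1e-3, 10)], seed=7)
    b = fit_mle(nll, [(-5, 5), (0, 2), (1e-3, 10)], seed=7)
    assert np.array_equal(a[0], b[0]) and a[1] == b[1]
    assert a[0][2] >= 1e-3


def test_fit_mle_rejects_bad_bounds():
    with pytest.raises(ValueError):
        fit_mle(lambda p: 0.0, [(0, np.inf)])


def test_grid_fit_single_point_and_ordering():
    rng = np.random.default_rng(5)
    y = 1.5 + rng.normal(0, 1, 60)

    evals = {}

    def factory(g):
        def nll(p):
            v = float(np.sum((y - p[0]) ** 2)) + (g - 1.0) ** 2 * 100
            return v

        evals[g] = nll
        return nll

    g, x, f = grid_fit(factory, [0.5, 1.0, 2.0], [(-5, 5)], n_starts=3, seed=0)
    assert g == 1.0
    single = grid_fit(factory, [2.0], [(-5, 5)], n_starts=3, seed=0)
    ref = fit_mle(factory(2.0), [(-5, 5)], n_starts=3, seed=0)
    assert single[2] == pytest.approx(ref[1], abs=1e-12)
    with pytest.raises(ValueError):
        grid_fit(factory, [], [(-5, 5)])


def _fit(subject, model, nll, k=3, n=162):
    return ModelFit(subject, model, "mode", {}, nll, n, k)


def test_delta_aicc_arithmetic_and_invariance():
    fits = [_fit(s, "A", 100.0) for s in range(16)] + [_fit(s, "B", 101.0) for s in range(16)]
    sums = delta_aicc(fits)
    assert sums["A"] == pytest.approx(0.0)
    assert sums["B"] == pytest.approx(32.0)
    shifted = [_fit(s, "A", 100.0 + s) for s in range(16)] + [
        _fit(s, "B", 101.0 + s) for s in range(16)
    ]
    assert delta_aicc(shifted) == sums
    with pytest.raises(ValueError):
        delta_aicc(fits + [_fit(99, "A", 1.0)])


def test_single_model_delta_is_zero():
    assert delta_aicc([_fit(s, "only", 50.0) for s in range(5)])["only"] == 0.0


def test_group_bms_symmetry_gives_uniform_pxp():
    L = np.full((10, 4), -3.0)
    sel = group_bms(L, seed=0)
    assert np.allclose(sel.pxp, 0.25, atol=0.01)
    assert sel.ep.sum() == pytest.approx(1.0, abs=1e-3)
    assert sel.pxp.sum() == pytest.approx(1.0, abs=1e-3)


def test_group_bms_dominant_model_wins():
    L = np.zeros((15, 2))
    L[:, 0] = 10.0
    sel = group_bms(L, seed=0)
    assert sel.pxp[0] > 0.99
    assert sel.bor < 0.01


def test_group_bms_two_model_ep_matches_beta_cdf():
    """Sampled exceedance equals the closed-form Dirichlet(2) tail probability."""
    L = np.array([[0.0, 1.2]] * 6 + [[0.5, 0.0]] * 3)
    sel = group_bms(L, n_samples=200_000, seed=1)
    closed = 1 - stats.beta.cdf(0.5, sel.alpha[0], sel.alpha[1])
    assert sel.ep[0] == pytest.approx(closed, abs=0.005)
    assert sel.pxp == pytest.approx((1 - sel.bor) * sel.ep + sel.bor / 2, abs=1e-12)


def test_group_bms_rejects_bad_input():
    with pytest.raises(ValueError):
        group_bms(np.zeros((5, 1)))
    with pytest.raises(ValueError):
        group_bms(np.array([[np.inf, 0.0]]))
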