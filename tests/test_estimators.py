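"""Estimators: closed forms, Firth robustness, CIs, bias reduction."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import chi2

import firthiss as fi


def test_closed_form_2x2_examples():
    assert fi.fit_2x2_closed_form(2, 1, 1, 2, "ML") == pytest.approx(math.log(4))
    assert fi.fit_2x2_closed_form(2, 1, 1, 2, "FC") == pytest.approx(
        math.log(2.5 * 2.5 / (1.5 * 1.5))
    )
    assert math.isnan(fi.fit_2x2_closed_form(1, 1, 1, 0, "ML"))
    assert fi.fit_2x2_closed_form(1, 1, 1, 0, "FC") == pytest.approx(
        math.log(1.5 * 0.5 / (1.5 * 1.5))
    )
    with pytest.raises(ValueError):
        fi.fit_2x2_closed_form(0, 0, 0, 0)


def test_ml_fit_matches_closed_form_and_group_proportions():
    d = fi.dataset_from_2x2(6, 2, 3, 5)
    m = fi.ml_fit(d)
    assert m.converged and m.estimate_exists
    assert m.beta[1] == pytest.approx(fi.fit_2x2_closed_form(6, 2, 3, 5, "ML"), abs=1e-6)
    # fitted probabilities equal the observed event proportions per group
    p0, p1 = 3 / 9, 5 / 7
    x = d.X[:, 0]
    assert np.allclose(m.fitted_probabilities[x == 0], p0, atol=1e-6)
    assert np.allclose(m.fitted_probabilities[x == 1], p1, atol=1e-6)


def test_ml_nonexistence_on_separated_data():
    m = fi.ml_fit(fi.dataset_from_2x2(5, 5, 5, 0))
    assert not m.estimate_exists and not m.converged
    assert np.all(np.isnan(m.beta))


def test_firth_finite_on_completely_separated_continuous_data():
    x = np.arange(10.0)[:, None]
    y = (np.arange(10) >= 5).astype(int)
    assert fi.detect_separation((x, y)).kind == "complete"
    f = fi.firth_fit(fi.Dataset(x, y, 10))
    assert np.all(np.isfinite(f.beta))
    assert np.all((f.fitted_probabilities > 0) & (f.fitted_probabilities < 1))


def test_firth_balanced_null_is_symmetric():
    f = fi.firth_fit(fi.dataset_from_2x2(3, 3, 3, 3))
    assert f.beta[1] == pytest.approx(0.0, abs=1e-8)


def test_weighted_fit_equals_expanded_fit():
    cells = (4, 2, 1, 3)
    d = fi.dataset_from_2x2(*cells)
    Xw = np.array([[0.0], [1.0], [0.0], [1.0]])
    yw = np.array([0.0, 0.0, 1.0, 1.0])
    w = np.array(cells, float)
    fw = fi.firth_fit((Xw, yw), weights=w)
    fe = fi.firth_fit(d)
    assert np.allclose(fw.beta, fe.beta, atol=1e-6)
    mw = fi.ml_fit((Xw, yw), weights=w)
    me = fi.ml_fit(d)
    assert np.allclose(mw.beta, me.beta, atol=1e-6)


def _profile_pll_oracle(x, y, b1):
    """Directly maximize the penalized likelihood over the intercept at fixed
    slope, computing l + 0.5*logdet(X'WX) from first principles."""
    X1 = np.column_stack([np.ones_like(x), x])

    def neg_pll(b0):
        eta = b0 + b1 * x
        pi = expit(eta)
        w = pi * (1 - pi)
        info = X1.T @ (X1 * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -(ll + 0.5 * logdet)

    res = minimize_scalar(neg_pll, bounds=(-30, 30), method="bounded",
                          options={"xatol": 1e-10})
    return -res.fun


def test_profile_ci_matches_grid_oracle():
    d = fi.dataset_from_2x2(3, 4, 5, 2)
    x, y = d.X[:, 0], d.y.astype(float)
    f = fi.firth_fit(d)
    lo, hi = fi.profile_penalized_ci(d, f, 1)
    # oracle: scan the profile on a fine grid and interpolate the chi2 cutoff
    grid = np.linspace(f.beta[1] - 4, f.beta[1] + 4, 1601)
    pll = np.array([_profile_pll_oracle(x, y, b) for b in grid])
    g = 2 * (pll.max() - pll) - chi2.ppf(0.95, 1)
    left = grid[grid < f.beta[1]]
    right = grid[grid >= f.beta[1]]
    lo_oracle = np.interp(0.0, -g[: len(left)], left)
    hi_oracle = np.interp(0.0, g[len(left):], right)
    assert lo == pytest.approx(lo_oracle, abs=5e-3)
    assert hi == pytest.approx(hi_oracle, abs=5e-3)


def test_profile_ci_contains_estimate_and_widens_with_level():
    d = fi.dataset_from_2x2(5, 5, 5, 1)
    f = fi.firth_fit(d)
    lo95, hi95 = fi.profile_penalized_ci(d, f, 1, level=0.95)
    assert lo95 < f.beta[1] < hi95
    f2 = fi.firth_fit(d)
    lo99, hi99 = fi.profile_penalized_ci(d, f2, 1, level=0.99)
    assert lo99 < lo95 and hi99 > hi95


def test_wald_symmetric_profile_need_not_be():
    d = fi.dataset_from_2x2(8, 3, 2, 1)
    m = fi.ml_fit(d)
    assert (m.ci_upper[1] - m.beta[1]) == pytest.approx(m.beta[1] - m.ci_lower[1])
    f = fi.firth_fit(d)
    lo, hi = fi.profile_penalized_ci(d, f, 1)
    assert abs((hi - f.beta[1]) - (f.beta[1] - lo)) > 1e-3


def test_firth_slope_equivariant_under_rescaling(rng):
    sampler = fi.ScenarioSampler(2, 1.39, 0.25, n_calib=10**5)
    d = sampler.sample(60, rng)
    f = fi.firth_fit(d)
    scaled = fi.Dataset(d.X * np.array([2.0, 5.0]), d.y, d.n)
    fs = fi.firth_fit(scaled)
    assert fs.beta[1] == pytest.approx(f.beta[1] / 2.0, rel=1e-5)
    assert fs.beta[2] == pytest.approx(f.beta[2] / 5.0, rel=1e-5)


def test_ml_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    sampler = fi.ScenarioSampler(5, 0.35, 0.25, n_calib=10**5)
    d = sampler.sample(400, rng)
    assert not fi.detect_separation(d).separated
    m = fi.ml_fit(d)
    X1 = np.column_stack([np.ones(d.n), d.X])
    ref = sm.Logit(d.y, X1).fit(disp=0)
    assert np.allclose(m.beta, ref.params, atol=1e-5)
    assert np.allclose(m.se, ref.bse, atol=1e-4)


def test_firth_reduces_small_sample_bias_vs_ml():
    """Mean Firth estimate is closer to the truth than mean ML over the
    non-separated replications (N=200, K=2, beta1=0.35)."""
    sampler = fi.ScenarioSampler(2, 0.35, 0.25, n_calib=10**5)
    fc, ml = [], []
    for r in range(2000):
        d = sampler.sample(200, np.random.default_rng((77, r)))
        fc.append(fi.firth_fit(d).beta[1])
        m = fi.ml_fit(d)
        if m.estimate_exists:
            ml.append(m.beta[1])
    assert len(ml) > 1500
    assert abs(np.mean(fc) - 0.35) < abs(np.mean(ml) - 0.35)
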