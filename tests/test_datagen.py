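"""Generator: latent correlation structure, transforms, calibrations."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

import firthiss as fi
from firthiss.datagen import (
    _SEXTILE_SPANS,
    CovariateSpec,
    EffectVector,
    compute_truncation_cap,
)

# Frozen one-time eigendecomposition of the default latent correlation matrix.
SIGMA_MIN_EIG = 0.028552431674723894


def test_sigma_matches_documented_structure():
    sigma = fi.build_sigma()
    assert sigma.shape == (10, 10)
    assert np.allclose(sigma, sigma.T)
    assert np.all(np.diag(sigma) == 1.0)
    assert sigma[0, 1] == 0.6  # z1-z2
    assert sigma[2, 3] == -0.5  # z3-z4
    assert sigma[3, 8] == 0.3  # z4-z9
    assert sigma[9, :9].sum() == 0.0  # z10 uncorrelated
    # 14 listed pairs, everything else zero
    off = sigma[np.triu_indices(10, k=1)]
    assert np.count_nonzero(off) == 14
    assert np.isclose(np.linalg.eigvalsh(sigma)[0], SIGMA_MIN_EIG, rtol=1e-9)


def test_sigma_rejects_bad_listings():
    bad = (
        CovariateSpec(1, "binary-threshold", (0.0,), ((2, 0.6),), 0.5),
        CovariateSpec(2, "binary-threshold", (0.0,), ((1, 0.5),), 0.5),
    )
    with pytest.raises(ValueError, match="asymmetric"):
        fi.build_sigma(bad)
    nonpd = (
        CovariateSpec(1, "binary-threshold", (0.0,), ((2, 0.99), (3, 0.99)), 0.5),
        CovariateSpec(2, "binary-threshold", (0.0,), ((1, 0.99), (3, -0.99)), 0.5),
        CovariateSpec(3, "binary-threshold", (0.0,), ((1, 0.99), (2, -0.99)), 0.5),
    )
    with pytest.raises(ValueError, match="positive definite"):
        fi.build_sigma(nonpd)


def test_transform_pointwise_examples():
    z = np.zeros(10)
    x = fi.transform_latent(z)
    assert x[0] == 1.0  # 0 < 0.84
    assert x[4] == 1.0  # -1.2 <= 0 < 0.75
    assert x[6] == 55.0
    z6 = np.zeros(10)
    z6[5] = 1.0
    assert fi.transform_latent(z6)[5] == 1.0  # middle ordinal level
    z8 = np.zeros(10)
    z8[7] = -10.0  # 100*e^-10 < 20 -> floored at 0
    assert fi.transform_latent(z8)[7] == 0.0


def test_transformed_means_match_documented_expectations(rng):
    n = 10**6
    chol = np.linalg.cholesky(fi.build_sigma())
    z = rng.standard_normal((n, 10)) @ chol.T
    x = fi.transform_latent(z)
    for j, spec in enumerate(fi.DEFAULT_SCHEME):
        mc_se = x[:, j].std() / math.sqrt(n)
        # documented expectations are rounded to 2 dp
        assert abs(x[:, j].mean() - spec.expected_value) < 3 * mc_se + 0.005, (
            f"covariate {spec.index}"
        )


def test_latent_correlations_recovered(rng):
    n = 200_000
    chol = np.linalg.cholesky(fi.build_sigma())
    z = rng.standard_normal((n, 10)) @ chol.T
    emp = np.corrcoef(z.T)
    assert np.allclose(emp, fi.build_sigma(), atol=3.5 / math.sqrt(n) + 0.004)


def test_truncation_clamps_only_the_upper_tail():
    assert fi.truncate_continuous(100.0, cap=126.0) == 100.0
    assert fi.truncate_continuous(500.0, cap=126.0) == 126.0
    # frozen caps equal the exact discrete quantile construction and are
    # consistent with the Monte-Carlo oracle (x9's Q3 sits on a CDF jump, so
    # the sampled cap can land 5*IQR+1 ~ 6 away)
    for spec in fi.DEFAULT_SCHEME:
        if spec.is_continuous:
            assert fi.theoretical_truncation_cap(spec) == fi.TRUNCATION_CAPS[spec.index]
            cap = compute_truncation_cap(spec, n_draws=10**6, seed=99)
            assert abs(cap - fi.TRUNCATION_CAPS[spec.index]) <= 7.0
    # truncation affects only a small upper-tail fraction (< 2%)
    z = np.random.default_rng(3).standard_normal(10**6)
    x8 = np.maximum(0.0, np.floor(100 * np.exp(z)) - 20)
    assert 0.0 < np.mean(x8 > fi.TRUNCATION_CAPS[8]) < 0.02


def test_continuous_effect_calibration():
    # symmetric age-like covariate: span ~ floor-adjusted 2*10*z_{5/6}
    spec10 = fi.DEFAULT_SCHEME[9]
    beta10 = fi.calibrate_continuous_effect(spec10, n_draws=10**6, seed=7)
    direct_span = np.floor(10 * norm.ppf(5 / 6) + 55) - np.floor(10 * norm.ppf(1 / 6) + 55)
    assert beta10 == pytest.approx(math.log(2) / direct_span, rel=0.02)
    assert fi.CONTINUOUS_EFFECTS[10] == pytest.approx(math.log(2) / _SEXTILE_SPANS[10])
    # linearity in the target log odds ratio
    double = fi.calibrate_continuous_effect(spec10, target_log_or=2 * math.log(2),
                                            n_draws=10**5, seed=7)
    single = fi.calibrate_continuous_effect(spec10, target_log_or=math.log(2),
                                            n_draws=10**5, seed=7)
    assert double == pytest.approx(2 * single)
    # heavier-tailed lab-like covariate has the wider sextile span
    assert fi.CONTINUOUS_EFFECTS[8] < fi.CONTINUOUS_EFFECTS[10]


def test_intercept_calibration_closed_form_cases():
    empty = EffectVector(beta0=math.nan, beta=np.empty(0))
    assert fi.calibrate_intercept(empty, 0.25) == pytest.approx(logit(0.25), abs=1e-4)
    assert fi.calibrate_intercept(empty, 0.5) == pytest.approx(0.0, abs=1e-4)
    with pytest.raises(ValueError):
        fi.calibrate_intercept(empty, 1.5)


def test_intercept_monotone_in_target_rate():
    eff = fi.make_effects(5, 1.39)
    b_low = fi.calibrate_intercept(eff, 0.1, n_calib=10**5)
    b_high = fi.calibrate_intercept(eff, 0.25, n_calib=10**5)
    assert b_low < b_high


def test_event_rate_self_consistency(rng):
    """The calibrated intercept reproduces the target marginal event rate."""
    sampler = fi.ScenarioSampler(10, 1.39, 0.1, n_calib=10**6)
    d = sampler.sample(10**5, rng)
    assert d.y.mean() == pytest.approx(0.1, abs=0.005)
    assert d.X[:, 0].mean() == pytest.approx(0.8, abs=0.01)


def test_sampling_reproducible_and_extension_bookkeeping():
    sampler = fi.ScenarioSampler(2, 0.35, 0.25, n_calib=10**5)
    d1 = fi.sample_dataset(sampler, 50, seed=123)
    d2 = fi.sample_dataset(sampler, 50, seed=123)
    assert np.array_equal(d1.X, d2.X) and np.array_equal(d1.y, d2.y)
    ext = fi.extend_dataset(sampler, d1, 7, seed=5)
    assert ext.n == 57 and ext.n_original == 50
    assert np.array_equal(ext.X[:50], d1.X)
    with pytest.raises(ValueError):
        fi.extend_dataset(sampler, d1, 0, seed=5)


def test_extension_rows_share_the_generating_distribution():
    sampler = fi.ScenarioSampler(5, 0.0, 0.25, n_calib=10**5)
    rng = np.random.default_rng(11)
    d = sampler.sample(10, rng)
    big = sampler.extend(d, 200_000, rng)
    new_x = big.X[10:]
    for j, spec in enumerate(fi.DEFAULT_SCHEME[:5]):
        se = new_x[:, j].std() / math.sqrt(len(new_x))
        assert abs(new_x[:, j].mean() - spec.expected_value) < 3 * se + 0.005


def test_dataset_csv_roundtrip_flags_iss_rows(tmp_path):
    sampler = fi.ScenarioSampler(2, 0.35, 0.25, n_calib=10**5)
    d = fi.sample_dataset(sampler, 20, seed=8)
    ext = fi.extend_dataset(sampler, d, 5, seed=9)
    path = tmp_path / "data.csv"
    fi.dataset_to_csv(ext, path)
    header = path.read_text().splitlines()[0]
    assert header == "x1,x2,y,iss_added"
    back = fi.dataset_from_csv(path)
    assert back.n == 25 and back.n_original == 20
    assert np.array_equal(back.X, ext.X) and np.array_equal(back.y, ext.y)
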