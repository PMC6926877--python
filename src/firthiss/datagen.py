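"""Synthetic covariate and outcome generation for separation-prone logistic models.

The default scheme emulates a typical epidemiological data set: ten latent
standard-normal variables with a sparse correlation structure are transformed
into four binary, two three-level ordinal and four continuous covariates
(age-like and skewed lab-value-like, truncated at Q3 + 5·IQR to avoid extreme
values).  The binary outcome is drawn from a logistic model whose intercept is
calibrated to a target marginal event rate and whose continuous-covariate
effects are calibrated so that the log odds ratio between the first and fifth
sextile of the covariate distribution equals log 2.

The first covariate, an unbalanced binary exposure with expectation 0.8, is
the target of inference throughout; the remaining covariates act as fixed
nuisance confounders (log 2 for binary, log √2 for ordinal covariates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "CovariateSpec",
    "Dataset",
    "EffectVector",
    "ScenarioSampler",
    "DEFAULT_SCHEME",
    "TRUNCATION_CAPS",
    "CONTINUOUS_EFFECTS",
    "build_sigma",
    "transform_latent",
    "truncate_continuous",
    "compute_truncation_cap",
    "theoretical_quantile",
    "theoretical_truncation_cap",
    "calibrate_continuous_effect",
    "nuisance_effects",
    "make_effects",
    "calibrate_intercept",
    "sample_dataset",
    "extend_dataset",
    "dataset_to_csv",
    "dataset_from_csv",
]

# Fixed internal seed for the one-time Monte-Carlo calibration of truncation
# caps, sextile spans and intercepts; independent of user-facing seeds.
_INTERNAL_SEED = 20_200_101


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate of the generating scheme.

    Parameters
    ----------
    index
        1-based covariate position.
    kind
        One of ``binary-threshold`` (I(z < t)), ``ordinal-two-thresholds``
        (I(z >= t1) + I(z >= t2)), ``affine-floor`` (⌊a·z + b⌋) or
        ``exp-shift-floor`` (max(0, ⌊a·e^z⌋ − c)).
    params
        Transform parameters in the order given above.
    correlations
        Pairs ``(partner_index, rho)`` of latent correlations; must be listed
        symmetrically on both partners.
    expected_value
        Documented expectation of the transformed covariate (sanity anchor).
    """

    index: int
    kind: str
    params: tuple
    correlations: tuple
    expected_value: float

    @property
    def is_continuous(self) -> bool:
        return self.kind in ("affine-floor", "exp-shift-floor")


DEFAULT_SCHEME: tuple[CovariateSpec, ...] = (
    CovariateSpec(1, "binary-threshold", (0.84,), ((2, 0.6), (3, 0.5), (7, 0.5)), 0.8),
    CovariateSpec(2, "binary-threshold", (-0.35,), ((1, 0.6),), 0.36),
    CovariateSpec(3, "binary-threshold", (0.0,), ((1, 0.5), (4, -0.5), (5, -0.3)), 0.5),
    CovariateSpec(
        4,
        "binary-threshold",
        (0.0,),
        ((3, -0.5), (5, 0.5), (7, 0.3), (8, 0.5), (9, 0.3)),
        0.5,
    ),
    CovariateSpec(
        5,
        "ordinal-two-thresholds",
        (-1.2, 0.75),
        ((3, -0.3), (4, 0.5), (8, 0.3), (9, 0.3)),
        1.11,
    ),
    CovariateSpec(6, "ordinal-two-thresholds", (0.5, 1.5), ((7, -0.3), (8, 0.3)), 0.37),
    CovariateSpec(7, "affine-floor", (10.0, 55.0), ((1, 0.5), (4, 0.3), (6, -0.3)), 54.5),
    CovariateSpec(
        8,
        "exp-shift-floor",
        (100.0, 20.0),
        ((4, 0.5), (5, 0.3), (6, 0.3), (9, 0.5)),
        138.58,
    ),
    CovariateSpec(
        9, "exp-shift-floor", (80.0, 20.0), ((4, 0.3), (5, 0.3), (8, 0.5)), 106.97
    ),
    CovariateSpec(10, "affine-floor", (10.0, 55.0), (), 54.5),
)

# Truncation caps Q3 + 5·IQR of each continuous covariate's marginal
# distribution.  The floored covariates are integer-valued with closed-form
# CDFs through the normal CDF, so the caps are frozen from the exact discrete
# quantiles (theoretical_quantile); compute_truncation_cap provides the
# Monte-Carlo cross-check.  x9's Q3 sits almost exactly on a CDF jump
# (P(x9 <= 136) = 0.74998), which makes sampled quantiles unstable there —
# another reason to freeze the exact values.
TRUNCATION_CAPS: dict[int, float] = {7: 126.0, 8: 906.0, 9: 722.0, 10: 126.0}

# Sextile spans q_{5/6} - q_{1/6} of the truncated covariate distributions,
# exact discrete quantiles as above (truncation does not reach the sextiles).
_SEXTILE_SPANS: dict[int, float] = {7: 19.0, 8: 225.0, 9: 180.0, 10: 19.0}

# Effects calibrated so that the first-vs-fifth-sextile log odds ratio is log 2.
CONTINUOUS_EFFECTS: dict[int, float] = {
    k: math.log(2) / span for k, span in _SEXTILE_SPANS.items()
}


def build_sigma(specs: tuple[CovariateSpec, ...] = DEFAULT_SCHEME) -> np.ndarray:
    """Assemble the latent correlation matrix from the per-covariate lists.

    Raises ``ValueError`` if the listed correlations are asymmetric or if the
    resulting matrix is not positive definite.
    """
    p = len(specs)
    indices = sorted(s.index for s in specs)
    if indices != list(range(1, p + 1)):
        raise ValueError(f"specs must cover indices 1..{p}, got {indices}")
    sigma = np.eye(p)
    listed: dict[tuple[int, int], float] = {}
    for s in specs:
        for partner, rho in s.correlations:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation {rho} outside [-1, 1]")
            listed[(s.index, partner)] = rho
    for (i, j), rho in listed.items():
        if listed.get((j, i)) != rho:
            raise ValueError(f"asymmetric correlation listing for pair ({i}, {j})")
        sigma[i - 1, j - 1] = rho
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin <= 0:
        raise ValueError(f"latent correlation matrix not positive definite (min eig {eigmin})")
    return sigma


def _apply_transform(z: np.ndarray, spec: CovariateSpec) -> np.ndarray:
    if spec.kind == "binary-threshold":
        (t,) = spec.params
        return (z < t).astype(float)
    if spec.kind == "ordinal-two-thresholds":
        t1, t2 = spec.params
        return (z >= t1).astype(float) + (z >= t2).astype(float)
    if spec.kind == "affine-floor":
        a, b = spec.params
        return np.floor(a * z + b)
    if spec.kind == "exp-shift-floor":
        a, c = spec.params
        return np.maximum(0.0, np.floor(a * np.exp(z)) - c)
    raise ValueError(f"unknown transform kind {spec.kind!r}")


def truncate_continuous(x: np.ndarray | float, cap: float) -> np.ndarray | float:
    """Clamp a continuous covariate at its cap (Q3 + 5·IQR)."""
    return np.minimum(x, cap)


def transform_latent(
    z: np.ndarray,
    specs: tuple[CovariateSpec, ...] = DEFAULT_SCHEME,
    caps: dict[int, float] | None = None,
) -> np.ndarray:
    """Map latent normal draws to covariates, including truncation.

    ``z`` has shape (n, p) or (p,); the result has the same shape.
    """
    if caps is None:
        caps = TRUNCATION_CAPS
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zz = np.atleast_2d(z)
    if zz.shape[1] != len(specs):
        raise ValueError(f"expected {len(specs)} latent columns, got {zz.shape[1]}")
    x = np.empty_like(zz)
    for j, spec in enumerate(specs):
        col = _apply_transform(zz[:, j], spec)
        if spec.is_continuous and spec.index in caps:
            col = truncate_continuous(col, caps[spec.index])
        x[:, j] = col
    return x[0] if single else x


def theoretical_quantile(spec: CovariateSpec, p: float) -> float:
    """Exact quantile of a continuous covariate's (integer-valued) marginal.

    Returns the smallest integer t with P(X <= t) >= p, using the closed-form
    CDF of the floored transform of a standard normal.
    """
    from scipy.stats import norm

    if not spec.is_continuous:
        raise ValueError("theoretical quantiles implemented for continuous covariates")
    if spec.kind == "affine-floor":
        a, b = spec.params
        t = np.arange(math.floor(b - 10 * a), math.ceil(b + 10 * a))
        cdf = norm.cdf((t + 1 - b) / a)
    else:
        a, c = spec.params
        t = np.arange(0, int(a * math.exp(8)))
        cdf = norm.cdf(np.log((t + c + 1) / a))
    return float(t[np.argmax(cdf >= p)])


def theoretical_truncation_cap(spec: CovariateSpec) -> float:
    """Exact Q3 + 5·IQR cap from the closed-form marginal distribution."""
    q1 = theoretical_quantile(spec, 0.25)
    q3 = theoretical_quantile(spec, 0.75)
    return q3 + 5.0 * (q3 - q1)


def compute_truncation_cap(
    spec: CovariateSpec, n_draws: int = 10**7, seed: int = _INTERNAL_SEED
) -> float:
    """Monte-Carlo estimate of the Q3 + 5·IQR truncation cap for one covariate.

    Cross-check for the frozen exact caps; near CDF jumps the sampled
    quantile can land one integer off the exact one.
    """
    if not spec.is_continuous:
        raise ValueError("truncation caps apply to continuous covariates only")
    z = np.random.default_rng(seed).standard_normal(n_draws)
    x = _apply_transform(z, spec)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(q3 + 5.0 * (q3 - q1))


def calibrate_continuous_effect(
    spec: CovariateSpec,
    target_log_or: float = math.log(2),
    n_draws: int = 10**7,
    seed: int = _INTERNAL_SEED,
    cap: float | None = None,
) -> float:
    """Effect size giving ``target_log_or`` between the 1st and 5th sextile.

    Returns ``target_log_or / (q_{5/6} - q_{1/6})`` of the truncated covariate
    distribution, estimated by Monte Carlo.  Raises if the sextiles coincide.
    """
    if cap is None:
        cap = TRUNCATION_CAPS.get(spec.index, math.inf)
    z = np.random.default_rng(seed).standard_normal(n_draws)
    x = np.minimum(_apply_transform(z, spec), cap)
    q_lo, q_hi = np.quantile(x, [1.0 / 6.0, 5.0 / 6.0])
    if q_hi <= q_lo:
        raise ValueError(f"degenerate sextile span for covariate {spec.index}")
    return float(target_log_or / (q_hi - q_lo))


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------

_BINARY_EFFECT = math.log(2)
_ORDINAL_EFFECT = math.log(math.sqrt(2))


@dataclass(frozen=True)
class EffectVector:
    """Coefficients of the generating logistic model: intercept + K slopes."""

    beta0: float
    beta: np.ndarray  # length K; beta[0] is the target effect

    @property
    def K(self) -> int:
        return len(self.beta)


def nuisance_effects(K: int, specs: tuple[CovariateSpec, ...] = DEFAULT_SCHEME) -> np.ndarray:
    """Fixed effects for covariates 2..K: log 2 (binary), log √2 (ordinal),
    sextile-calibrated (continuous)."""
    out = np.empty(max(K - 1, 0))
    for j in range(1, K):
        spec = specs[j]
        if spec.kind == "binary-threshold":
            out[j - 1] = _BINARY_EFFECT
        elif spec.kind == "ordinal-two-thresholds":
            out[j - 1] = _ORDINAL_EFFECT
        else:
            out[j - 1] = CONTINUOUS_EFFECTS[spec.index]
    return out


def make_effects(K: int, beta1: float, beta0: float = math.nan) -> EffectVector:
    """Effect vector with the target effect ``beta1`` and fixed nuisance effects."""
    beta = np.concatenate([[beta1], nuisance_effects(K)])
    return EffectVector(beta0=beta0, beta=beta)


# One shared calibration covariate sample (all 10 columns), keyed by size.
_CALIB_CACHE: dict[int, np.ndarray] = {}
_INTERCEPT_CACHE: dict[tuple, float] = {}


def _calibration_covariates(n_calib: int, seed: int) -> np.ndarray:
    key = (n_calib, seed)
    if key not in _CALIB_CACHE:
        rng = np.random.default_rng(seed)
        chol = np.linalg.cholesky(build_sigma())
        z = rng.standard_normal((n_calib, 10)) @ chol.T
        _CALIB_CACHE[key] = transform_latent(z)
    return _CALIB_CACHE[key]


def calibrate_intercept(
    effects: EffectVector,
    target_rate: float,
    n_calib: int = 10**6,
    seed: int = _INTERNAL_SEED,
    tol: float = 1e-4,
) -> float:
    """Intercept giving marginal event rate ``target_rate`` under the model.

    Root-finds mean(expit(b0 + X·beta)) − target_rate on a fixed calibration
    sample of covariate draws; the sample (and hence the intercept) is shared
    across scenarios so that only the effect vector varies.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must be in (0, 1)")
    key = (effects.K, tuple(np.round(effects.beta, 12)), target_rate, n_calib, seed)
    if key in _INTERCEPT_CACHE:
        return _INTERCEPT_CACHE[key]
    if effects.K == 0:
        eta = np.zeros(1)
    else:
        x = _calibration_covariates(n_calib, seed)[:, : effects.K]
        eta = x @ effects.beta
    lo, hi = -40.0, 25.0

    def g(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target_rate

    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("intercept search range does not bracket the target rate")
    b0 = brentq(g, lo, hi, xtol=tol / 10)
    _INTERCEPT_CACHE[key] = float(b0)
    return float(b0)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dataset:
    """Covariate matrix, binary outcome, and the pre-extension sample size.

    Rows ``0..n_original-1`` are the original sample; any rows beyond were
    appended by sample-size escalation.
    """

    X: np.ndarray
    y: np.ndarray
    n_original: int

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def K(self) -> int:
        return self.X.shape[1]

    def head(self, n: int) -> "Dataset":
        """First ``n`` rows (keeps n_original capped accordingly)."""
        return Dataset(self.X[:n], self.y[:n], min(self.n_original, n))


class ScenarioSampler:
    """Sampler bound to one generating model (K covariates, calibrated effects).

    All 10 latent variables are always drawn from the full correlation matrix
    and the trailing covariates discarded for K < 10, so the target covariate's
    joint distribution with the retained confounders is identical across K.
    """

    def __init__(
        self,
        K: int,
        beta1: float,
        target_rate: float,
        specs: tuple[CovariateSpec, ...] = DEFAULT_SCHEME,
        beta0: float | None = None,
        n_calib: int = 10**6,
    ):
        if not 1 <= K <= len(specs):
            raise ValueError(f"K must be in 1..{len(specs)}")
        self.specs = specs
        self.K = K
        self.target_rate = target_rate
        self.sigma = build_sigma(specs)
        self._chol = np.linalg.cholesky(self.sigma)
        eff = make_effects(K, beta1)
        if beta0 is None:
            beta0 = calibrate_intercept(eff, target_rate, n_calib=n_calib)
        self.effects = replace(eff, beta0=beta0)

    def draw_covariates(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, len(self.specs))) @ self._chol.T
        return transform_latent(z, self.specs)[:, : self.K]

    def sample(self, n: int, rng: np.random.Generator) -> Dataset:
        """Draw a fresh dataset of ``n`` observations."""
        x = self.draw_covariates(n, rng)
        pi = expit(self.effects.beta0 + x @ self.effects.beta)
        y = (rng.random(n) < pi).astype(np.int8)
        return Dataset(x, y, n)

    def extend(self, d: Dataset, batch: int, rng: np.random.Generator) -> Dataset:
        """Append ``batch`` new observations from the same distribution."""
        if batch < 1:
            raise ValueError("batch must be >= 1")
        extra = self.sample(batch, rng)
        return Dataset(
            np.vstack([d.X, extra.X]),
            np.concatenate([d.y, extra.y]),
            d.n_original,
        )


def dataset_to_csv(d: Dataset, path) -> None:
    """Write a dataset as CSV: columns x1..xK, y, and an ``iss_added`` flag
    marking rows appended by sample-size escalation."""
    import pandas as pd

    cols = {f"x{j + 1}": d.X[:, j] for j in range(d.K)}
    cols["y"] = d.y.astype(int)
    cols["iss_added"] = (np.arange(d.n) >= d.n_original).astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def dataset_from_csv(path) -> Dataset:
    """Read a dataset written by :func:`dataset_to_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    xcols = sorted((c for c in df.columns if c.startswith("x")),
                   key=lambda c: int(c[1:]))
    X = df[xcols].to_numpy(float)
    y = df["y"].to_numpy(np.int8)
    if "iss_added" in df.columns:
        n_original = int((df["iss_added"] == 0).sum())
    else:
        n_original = len(df)
    return Dataset(X, y, n_original)


def sample_dataset(
    sampler: ScenarioSampler, n: int, seed: int | np.random.Generator
) -> Dataset:
    """Functional wrapper around :meth:`ScenarioSampler.sample`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sampler.sample(n, rng)


def extend_dataset(
    sampler: ScenarioSampler,
    d: Dataset,
    batch: int,
    seed: int | np.random.Generator,
) -> Dataset:
    """Functional wrapper around :meth:`ScenarioSampler.extend`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sampler.extend(d, batch, rng)
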