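"""Logistic regression by maximum likelihood and by Firth's penalized likelihood.

Firth's correction maximizes l(β) + ½·log det I(β), the log-likelihood
penalized by the Jeffreys invariant prior, which removes the first-order bias
of ML and yields finite estimates even under separation.  Confidence
intervals: Wald for ML, profile penalized-likelihood for Firth fits (the drop
in penalized log-likelihood along the profile is compared to a χ²₁ cutoff).

For the one-binary-covariate case the 2×2-table closed forms are provided:
the ML log odds ratio log(f00·f11 / (f01·f10)), and Firth's estimate, which
for 2×2 tables equals ML after adding 0.5 to every cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2

from .datagen import Dataset
from .separation import detect_separation

__all__ = [
    "ModelFit",
    "ConvergenceError",
    "ml_fit",
    "firth_fit",
    "profile_penalized_ci",
    "fit_2x2_closed_form",
    "dataset_from_2x2",
]

_Z975 = 1.959964  # two-sided 95% normal quantile
_SCORE_TOL = 1e-6
_STEP_TOL = 1e-6
_MAX_ITER = 250
_MAX_HALVINGS = 10


class ConvergenceError(RuntimeError):
    """Raised when the iteration cap is exceeded without convergence."""


@dataclass
class ModelFit:
    """Result of a logistic model fit (intercept first in all vectors)."""

    method: str  # 'ML' | 'FC'
    beta: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    ci_method: str  # 'wald' | 'profile-penalized-likelihood'
    loglik: float  # penalized log-likelihood for FC
    converged: bool
    iterations: int
    fitted_probabilities: np.ndarray
    estimate_exists: bool = True
    ci_flags: list = field(default_factory=list)  # e.g. unbounded profile sides


def _as_design(d) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(d, Dataset):
        X, y = d.X, d.y
    else:
        X, y = d
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.column_stack([np.ones(len(y)), X]), y


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(ll.sum() if w is None else (w * ll).sum())


def _check_rank(X1: np.ndarray) -> None:
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("design matrix (with intercept) is rank deficient")


# Both estimators are exactly equivariant under affine reparametrization of
# the covariates (for Firth the Jeffreys penalty shifts by a constant), so
# fits run on centered, unit-scale columns for Newton conditioning and map
# back afterwards.  Steps are capped at _MAX_STEP per component on the
# standardized scale to prevent overshoot oscillation on flat likelihoods.
_MAX_STEP = 5.0


def _standardize(X1: np.ndarray):
    """Center and scale the non-intercept columns; returns (Xs, mu, sd)."""
    mu = X1.mean(axis=0)
    sd = X1.std(axis=0)
    mu[0] = 0.0
    sd[0] = 1.0
    sd[sd == 0] = 1.0
    return (X1 - mu) / sd, mu, sd


def _backmap_matrix(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """A with beta_raw = A @ beta_standardized."""
    A = np.diag(1.0 / sd)
    A[0, 0] = 1.0
    A[0, 1:] = -mu[1:] / sd[1:]
    return A


def _cap_step(step: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(step))
    return step if m <= _MAX_STEP else step * (_MAX_STEP / m)


def ml_fit(d, check_separation: bool = True, weights: np.ndarray | None = None) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald 95% confidence intervals.

    If the data are separated the ML estimate does not exist (it diverges to
    ±infinity); this is detected up front and reported as a non-converged fit
    with ``estimate_exists=False`` rather than by letting the iteration drift.
    """
    X1, y = _as_design(d)
    _check_rank(X1)
    p = X1.shape[1]
    if check_separation and weights is None:
        rep = detect_separation((X1[:, 1:], y), classify=False)
        if rep.separated:
            nan = np.full(p, np.nan)
            return ModelFit(
                "ML", nan, nan.copy(), nan.copy(), nan.copy(), "wald",
                math.nan, False, 0, np.full(len(y), np.nan), estimate_exists=False,
            )
    Xs, mu, sd = _standardize(X1)

    def state_at(beta):
        """(ll, score, info cholesky, pi), or None if info is degenerate."""
        eta = Xs @ beta
        pi = expit(eta)
        wdiag = pi * (1 - pi)
        if weights is not None:
            wdiag = wdiag * weights
        try:
            cf = cho_factor(Xs.T @ (Xs * wdiag[:, None]))
        except (LinAlgError, np.linalg.LinAlgError):
            return None
        resid = y - pi if weights is None else weights * (y - pi)
        return _loglik(eta, y, weights), Xs.T @ resid, cf, pi

    beta = np.zeros(p)
    state = state_at(beta)
    if state is None:
        raise ConvergenceError("singular information matrix in ML fit")
    it = 0
    ll_prev = -math.inf
    for it in range(1, _MAX_ITER + 1):
        ll, score, cf, pi = state
        # on nearly separated data the optimum is numerically flat: the score
        # vanishes but I^{-1}·score is noise-sized, so the step criterion
        # cannot fire — accept convergence once the likelihood stalls too
        if np.max(np.abs(score)) < _SCORE_TOL and abs(ll - ll_prev) < 1e-10:
            break
        ll_prev = ll
        step = _cap_step(cho_solve(cf, score))
        new = state_at(beta + step)
        h = 0
        # reject steps that lower the likelihood or degenerate the information
        while (new is None or new[0] < ll - 1e-12) and h < _MAX_HALVINGS:
            step /= 2.0
            new = state_at(beta + step)
            h += 1
        if new is None:
            raise ConvergenceError("information matrix degenerate along the ML step")
        beta = beta + step
        state = new
        if np.max(np.abs(score)) < _SCORE_TOL and np.max(np.abs(step)) < _STEP_TOL:
            break
    else:
        raise ConvergenceError(f"ML fit did not converge in {_MAX_ITER} iterations")
    ll, _, cf, pi = state
    cov_s = cho_solve(cf, np.eye(p))
    A = _backmap_matrix(mu, sd)
    beta_raw = A @ beta
    se = np.sqrt(np.diag(A @ cov_s @ A.T))
    return ModelFit(
        "ML", beta_raw, se, beta_raw - _Z975 * se, beta_raw + _Z975 * se, "wald",
        ll, True, it, pi,
    )


def _firth_quantities(X1, y, beta, weights):
    """Penalized log-likelihood, modified score and information at ``beta``."""
    eta = X1 @ beta
    pi = expit(eta)
    wdiag = pi * (1 - pi)
    if weights is not None:
        wdiag = wdiag * weights
    info = X1.T @ (X1 * wdiag[:, None])
    cf = cho_factor(info)
    # hat diagonal h_i = w_i pi_i (1-pi_i) x_i' I^{-1} x_i
    sol = cho_solve(cf, X1.T)  # (p, n)
    hat = wdiag * np.einsum("ij,ji->i", X1, sol)
    resid = (y - pi if weights is None else weights * (y - pi)) + hat * (0.5 - pi)
    score = X1.T @ resid
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    pll = _loglik(eta, y, weights) + 0.5 * logdet
    return pll, score, info, cf, pi


def _try_firth_quantities(X1, y, beta, weights):
    """As :func:`_firth_quantities`, but ``None`` when the information matrix
    degenerates (all fitted probabilities at 0/1 — penalized likelihood -inf)."""
    try:
        return _firth_quantities(X1, y, beta, weights)
    except (LinAlgError, np.linalg.LinAlgError):
        return None


def _firth_solve(X1, y, free: np.ndarray, beta0: np.ndarray, weights=None,
                 max_iter: int = _MAX_ITER):
    """Maximize the penalized likelihood over ``beta[free]`` (others fixed)."""
    beta = beta0.copy()
    state = _try_firth_quantities(X1, y, beta, weights)
    if state is None:
        raise ConvergenceError("degenerate information matrix at the start value")
    pll, score, info, cf, pi = state
    for it in range(1, max_iter + 1):
        sub = info[np.ix_(free, free)]
        try:
            step_free = np.linalg.solve(sub, score[free])
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix in Firth fit")
        step = np.zeros_like(beta)
        step[free] = step_free
        step = _cap_step(step)
        new_beta = beta + step
        new = _try_firth_quantities(X1, y, new_beta, weights)
        h = 0
        while (new is None or new[0] < pll - 1e-12) and h < _MAX_HALVINGS:
            step /= 2.0
            new_beta = beta + step
            new = _try_firth_quantities(X1, y, new_beta, weights)
            h += 1
        if new is None:
            raise ConvergenceError("information matrix degenerate along the step")
        beta = new_beta
        pll, score, info, cf, pi = new
        if np.max(np.abs(score[free])) < _SCORE_TOL and np.max(np.abs(step)) < _STEP_TOL:
            return beta, pll, cf, pi, it, True
    raise ConvergenceError(f"Firth fit did not converge in {max_iter} iterations")


def firth_fit(d, weights: np.ndarray | None = None, ci: str | None = "wald") -> ModelFit:
    """Firth-penalized logistic fit (finite estimates even under separation).

    ``ci='wald'`` attaches Wald intervals from the inverse information at the
    penalized maximum; use :func:`profile_penalized_ci` for the
    profile-penalized-likelihood intervals used for inference.
    """
    X1, y = _as_design(d)
    _check_rank(X1)
    p = X1.shape[1]
    Xs, mu, sd = _standardize(X1)
    beta_s, pll_s, cf, pi, it, ok = _firth_solve(Xs, y, np.ones(p, bool),
                                                 np.zeros(p), weights)
    cov_s = cho_solve(cf, np.eye(p))
    A = _backmap_matrix(mu, sd)
    beta = A @ beta_s
    se = np.sqrt(np.diag(A @ cov_s @ A.T))
    # the penalty shifts by sum(log sd) under the reparametrization; report
    # the penalized log-likelihood on the raw scale
    pll = pll_s + float(np.sum(np.log(sd)))
    return ModelFit(
        "FC", beta, se, beta - _Z975 * se, beta + _Z975 * se, "wald",
        pll, ok, it, pi,
    )


def profile_penalized_ci(d, fit: ModelFit, j: int, level: float = 0.95,
                         max_offset: float = 50.0) -> tuple[float, float]:
    """Profile penalized-likelihood confidence interval for coefficient ``j``.

    Finds the two roots of 2·(l*(β̂) − l*_profile(β_j)) = χ²₁(level), where the
    profile maximizes the penalized likelihood over the other coefficients at
    fixed β_j.  If a root is not bracketed within ``max_offset`` of the
    estimate, that side is reported as unbounded (±inf) and flagged on the fit.
    """
    if fit.method != "FC":
        raise ValueError("profile penalized-likelihood CIs apply to Firth fits")
    X1, y = _as_design(d)
    p = X1.shape[1]
    free = np.ones(p, bool)
    free[j] = False
    cutoff = chi2.ppf(level, 1)
    Xs, mu, sd = _standardize(X1)
    if j == 0:
        # centering would turn "intercept fixed" into a cross-coordinate
        # constraint; scale-only keeps it a coordinate fix
        mu = np.zeros(p)
        Xs = X1 / sd
    shift = float(np.sum(np.log(sd)))
    pll_max_s = fit.loglik - shift
    bhat = float(fit.beta[j])
    # warm starts live on the standardized scale
    start0 = fit.beta * sd
    start0[0] = fit.beta[0] + float(fit.beta[1:] @ mu[1:])
    warm = {0: start0}

    def g(value: float) -> float:
        # warm-start the nuisance coefficients from the nearest solved profile
        key = min(warm, key=lambda k: abs(k - value))
        start = warm[key].copy()
        start[j] = value * sd[j]
        try:
            beta_s, pll_s, *_ = _firth_solve(Xs, y, free, start)
        except ConvergenceError:
            cold = np.zeros(p)
            cold[j] = value * sd[j]
            try:
                beta_s, pll_s, *_ = _firth_solve(Xs, y, free, cold)
            except ConvergenceError:
                # fixed value so extreme the model degenerates: the profile
                # penalized likelihood is effectively -inf there, i.e. far
                # beyond the confidence limit
                return 1e6
        warm[value] = beta_s
        return 2.0 * (pll_max_s - pll_s) - cutoff

    step0 = fit.se[j] if np.isfinite(fit.se[j]) and fit.se[j] > 0 else 1.0
    bounds = []
    for sign in (-1.0, 1.0):
        # memoize by offset so the bracket endpoints seen by brentq reproduce
        # the values found during expansion exactly (g warm-starts internally)
        memo: dict[float, float] = {0.0: -cutoff}

        def G(off: float) -> float:
            if off not in memo:
                memo[off] = g(bhat + sign * off)
            return memo[off]

        lo_off, hi_off = 0.0, 1.5 * step0
        found = False
        while hi_off <= max_offset:
            if G(hi_off) > 0:
                found = True
                break
            lo_off, hi_off = hi_off, hi_off * 2.0
        if not found:
            fit.ci_flags.append(f"profile CI unbounded on side {int(sign)} for coef {j}")
            bounds.append(sign * math.inf)
            continue
        root = brentq(G, lo_off, hi_off, xtol=1e-6, rtol=1e-10)
        bounds.append(bhat + sign * root)
    lower, upper = bounds[0], bounds[1]
    fit.ci_lower[j], fit.ci_upper[j] = lower, upper
    fit.ci_method = "profile-penalized-likelihood"
    return lower, upper


def fit_2x2_closed_form(f00: float, f01: float, f10: float, f11: float,
                        method: str = "ML") -> float:
    """Closed-form slope estimate for a 2×2 table.

    ML: log(f00·f11 / (f01·f10)), NaN when any cell is zero (the estimate does
    not exist).  FC: the same formula after adding 0.5 to every cell — exactly
    Firth's estimate in the 2×2 case.
    """
    cells = np.array([f00, f01, f10, f11], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be nonnegative")
    if cells.sum() == 0:
        raise ValueError("all-zero table")
    if method.upper() in ("FC", "FIRTH"):
        cells = cells + 0.5
    elif method.upper() != "ML":
        raise ValueError(f"unknown method {method!r}")
    if np.any(cells == 0):
        return math.nan
    f00, f01, f10, f11 = cells
    return float(math.log(f00 * f11 / (f01 * f10)))


def dataset_from_2x2(f00: int, f01: int, f10: int, f11: int) -> Dataset:
    """Expand a 2×2 table into an observation-level dataset.

    Cell ``f_yx`` counts observations with outcome ``y`` and covariate ``x``:
    f00=(y=0,x=0), f01=(y=0,x=1), f10=(y=1,x=0), f11=(y=1,x=1).
    """
    x = np.concatenate([np.zeros(f00), np.ones(f01), np.zeros(f10), np.ones(f11)])
    y = np.concatenate([np.zeros(f00 + f01), np.ones(f10 + f11)])
    return Dataset(x[:, None], y.astype(np.int8), len(y))
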