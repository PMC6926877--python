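"""Detection of complete and quasi-complete separation in logistic regression.

A dataset is separated when some coefficient vector b (including intercept)
satisfies (2·y_i − 1)·(b·[1, x_i]) >= 0 for every observation with strict
inequality for at least one; it is completely separated when a b exists with
strict inequality everywhere.  Separation makes the maximum-likelihood
estimate non-existent (coefficients diverge to ±infinity).

The decision is taken by linear programming over box-constrained directions,
the standard construction for separation checks in logistic regression.  A
slow exhaustive direction-grid search is provided as an independent oracle
for validating the LP on tiny problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .datagen import Dataset

__all__ = [
    "SeparationReport",
    "detect_separation",
    "separation_prevalence",
    "brute_force_separation",
]

# A direction weakly separates when all slacks are >= -_FEAS_TOL and the
# largest slack exceeds _SEP_TOL.
_FEAS_TOL = 1e-8
_SEP_TOL = 1e-6


@dataclass(frozen=True)
class SeparationReport:
    """Outcome of a separation check.

    ``direction`` is a separating coefficient vector (intercept first) on the
    original covariate scale when separated, else ``None``.
    """

    separated: bool
    kind: str  # 'none' | 'quasi-complete' | 'complete'
    direction: np.ndarray | None

    def conforms(self, x_row: np.ndarray, y_val: int) -> bool:
        """Whether a new observation is weakly consistent with ``direction``.

        If it is (slack >= 0; zero slack is enough because the previously
        strict rows stay strict), appending the observation leaves the dataset
        separated by the same direction, so the LP need not be re-solved.
        """
        if self.direction is None:
            raise ValueError("no separating direction available")
        s = 2 * int(y_val) - 1
        val = s * (self.direction[0] + float(x_row @ self.direction[1:]))
        return val >= -1e-10


def _as_xy(d) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(d, Dataset):
        return d.X, np.asarray(d.y)
    x, y = d
    return np.asarray(x, dtype=float), np.asarray(y)


def detect_separation(d, classify: bool = True) -> SeparationReport:
    """Classify a dataset as not separated, quasi-completely or completely
    separated.

    Accepts a :class:`~firthiss.datagen.Dataset` or an ``(X, y)`` pair.  The
    model is assumed to contain an intercept.  A dataset with only one outcome
    level is completely separated by the intercept alone.

    ``classify=False`` skips the second linear program that distinguishes
    complete from quasi-complete separation (the yes/no answer and the
    direction are unaffected); separated reports then carry
    ``kind='unclassified'``.
    """
    X, y = _as_xy(d)
    n = len(y)
    if n == 0:
        raise ValueError("empty dataset")
    Kp1 = X.shape[1] + 1
    s = (2 * y - 1).astype(float)
    if np.all(y == y[0]):
        direction = np.zeros(Kp1)
        direction[0] = s[0]
        return SeparationReport(True, "complete", direction)

    # Standardize columns for LP conditioning; intercept absorbs the centering.
    mu = X.mean(axis=0)
    scale = np.abs(X - mu).max(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mu) / scale
    A = s[:, None] * np.column_stack([np.ones(n), Xs])  # slacks = A @ b

    # Maximize total slack subject to slacks >= 0 and |b_j| <= 1.
    c = -A.sum(axis=0)
    res = linprog(c, A_ub=-A, b_ub=np.zeros(n), bounds=[(-1, 1)] * Kp1, method="highs")
    if res.status != 0:
        raise RuntimeError(f"separation LP failed: {res.message}")
    b = res.x
    slacks = A @ b
    if slacks.min() < -_FEAS_TOL or slacks.max() <= _SEP_TOL:
        return SeparationReport(False, "none", None)

    kind = "unclassified"
    if classify:
        # Complete iff a direction exists with all slacks strictly positive:
        # maximize t subject to A b >= t, |b_j| <= 1, t <= 1.
        c2 = np.zeros(Kp1 + 1)
        c2[-1] = -1.0
        A_ub = np.column_stack([-A, np.ones(n)])
        res2 = linprog(
            c2,
            A_ub=A_ub,
            b_ub=np.zeros(n),
            bounds=[(-1, 1)] * Kp1 + [(0, 1)],
            method="highs",
        )
        complete = res2.status == 0 and res2.x[-1] > _SEP_TOL
        if complete:
            b = res2.x[:-1]
        kind = "complete" if complete else "quasi-complete"
    # Map the direction back to the original covariate scale.
    direction = np.empty(Kp1)
    direction[1:] = b[1:] / scale
    direction[0] = b[0] - float((b[1:] * mu / scale).sum())
    return SeparationReport(True, kind, direction)


def separation_prevalence(reports: list[SeparationReport] | list[bool]) -> float:
    """Percentage of separated datasets in a collection of reports/flags."""
    if len(reports) == 0:
        raise ValueError("empty report list")
    flags = [r.separated if isinstance(r, SeparationReport) else bool(r) for r in reports]
    return 100.0 * sum(flags) / len(flags)


def brute_force_separation(d, step: float = 0.25) -> SeparationReport:
    """Exhaustive direction-grid separation check (validation oracle).

    Scans every direction with components on a grid of spacing ``step`` in
    [-1, 1]^{K+1}.  For binary covariates the vertices of the LP feasibility
    polytope have half-integer coordinates, so the default grid is exact
    there; for general data it is only a heuristic.  Exponential cost — tiny
    problems only.
    """
    X, y = _as_xy(d)
    n, K = X.shape
    s = (2 * y - 1).astype(float)
    A = s[:, None] * np.column_stack([np.ones(n), X])
    vals = np.arange(-1.0, 1.0 + step / 2, step)
    grid = np.array(list(itertools.product(vals, repeat=K + 1)))
    grid = grid[np.any(grid != 0, axis=1)]
    slacks = A @ grid.T  # (n, n_dirs)
    weak = np.all(slacks >= -1e-12, axis=0) & (slacks.max(axis=0) > 1e-12)
    strict = np.all(slacks > 1e-12, axis=0)
    if strict.any():
        return SeparationReport(True, "complete", grid[np.argmax(strict)])
    if weak.any():
        return SeparationReport(True, "quasi-complete", grid[np.argmax(weak)])
    return SeparationReport(False, "none", None)
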