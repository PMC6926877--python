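"""Analysis strategies for separated data: Firth on the original sample versus
increasing the sample size until separation disappears (ISS).

Three strategies are compared:

* ``FC`` — Firth's correction on the original data, profile
  penalized-likelihood CI;
* ``ML+ISS`` — draw additional observations from the generating distribution
  until the data are no longer separated, then ordinary ML with a Wald CI;
* ``FC+ISS`` — Firth's correction on the same escalated dataset.

Within a replication the two ISS strategies share the escalated dataset, so
strategy contrasts are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datagen import Dataset, ScenarioSampler
from .estimators import ModelFit, firth_fit, ml_fit, profile_penalized_ci
from .separation import SeparationReport, detect_separation

__all__ = ["StrategyResult", "IssAbortError", "run_iss", "run_strategy",
           "run_all_strategies", "STRATEGIES"]

STRATEGIES = ("FC", "ML+ISS", "FC+ISS")

# Rows are drawn from the replication stream in fixed-size blocks for speed;
# separation is still re-checked observation by observation (batch semantics).
_DRAW_BLOCK = 64


class IssAbortError(RuntimeError):
    """Raised when the escalation cap is hit while the data remain separated.

    Carries the partial dataset as ``partial``; signals a near-degenerate
    scenario rather than a numerical failure.
    """

    def __init__(self, message: str, partial: Dataset):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    fit: ModelFit
    n_original: int
    n_new: int
    was_separated: bool


def _row_generation_detect(Xall: np.ndarray, yall: np.ndarray,
                           active: list[int]) -> SeparationReport:
    """Separation check by row generation.

    Solves the LP on the ``active`` rows only and verifies the resulting
    direction against every row; violators join the active set and the LP is
    re-solved.  Sound because adding rows can only destroy separation: a
    non-separated subset certifies the whole dataset as non-separated, and a
    direction feasible for every row certifies separation.  ``active`` grows
    in place so successive checks reuse the accumulated support.
    """
    s = 2 * yall - 1
    known = set(active)
    while True:
        rep = detect_separation((Xall[active], yall[active]), classify=False)
        if not rep.separated:
            return rep
        slack = s * (rep.direction[0] + Xall @ rep.direction[1:])
        new = [int(v) for v in np.flatnonzero(slack < -1e-8) if v not in known]
        if not new:
            return rep
        active.extend(new)
        known.update(new)


def _scan_until_clear(d: Dataset, report: SeparationReport,
                      sampler: ScenarioSampler, rng: np.random.Generator,
                      max_total: int) -> Dataset:
    """Add observations one at a time until separation is removed.

    Appending an observation that is weakly consistent with the cached
    separating direction provably leaves the dataset separated (the direction
    still separates, and the previously strict rows stay strict), so the LP
    is re-solved — by row generation over the original rows plus past
    violators — only when the new row violates the cached direction.  The
    returned dataset is the minimal non-separated one on the path.
    """
    X_parts, y_parts = [d.X], [d.y]
    n = d.n
    active = list(range(d.n))
    while n < max_total:
        block = sampler.sample(min(_DRAW_BLOCK, max_total - n), rng)
        for i in range(block.n):
            X_parts.append(block.X[i : i + 1])
            y_parts.append(block.y[i : i + 1])
            n += 1
            if report.conforms(block.X[i], int(block.y[i])):
                continue  # still separated, same direction
            Xall = np.vstack(X_parts)
            yall = np.concatenate(y_parts)
            active.append(n - 1)
            report = _row_generation_detect(Xall, yall, active)
            if not report.separated:
                return Dataset(Xall, yall, d.n_original)
        if n >= max_total:
            break
    raise IssAbortError(
        f"still separated at the escalation cap ({max_total} observations)",
        Dataset(np.vstack(X_parts), np.concatenate(y_parts), d.n_original),
    )


def run_iss(d: Dataset, sampler: ScenarioSampler, rng: np.random.Generator,
            batch: int = 1, max_total: int | None = None) -> Dataset:
    """Escalate the sample until the separation check clears.

    ``batch`` observations are added between checks (default 1, which makes
    the returned sample size minimal).  For ``batch > 1`` the result is
    backtracked to the smallest non-separated prefix after the final batch.
    ``max_total`` caps the escalation (default 100× the original size).
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if max_total is None:
        max_total = 100 * d.n
    report = detect_separation(d, classify=False)
    if not report.separated:
        return d
    if batch == 1:
        return _scan_until_clear(d, report, sampler, rng, max_total)
    cur = d
    while cur.n < max_total:
        prev_n = cur.n
        cur = sampler.extend(cur, min(batch, max_total - cur.n), rng)
        report = detect_separation(cur, classify=False)
        if not report.separated:
            for m in range(prev_n + 1, cur.n):  # backtrack to the minimal prefix
                head = cur.head(m)
                if not detect_separation(head, classify=False).separated:
                    return head
            return cur
    raise IssAbortError(
        f"still separated at the escalation cap ({max_total} observations)", cur
    )


def _fc_result(d: Dataset, was_separated: bool, strategy: str = "FC",
               n_original: int | None = None) -> StrategyResult:
    fit = firth_fit(d)
    if d.K >= 1:
        profile_penalized_ci(d, fit, j=1)
    result_n0 = d.n_original if n_original is None else n_original
    return StrategyResult(strategy, fit, result_n0, d.n, was_separated)


def run_strategy(d: Dataset, sampler: ScenarioSampler, strategy: str,
                 rng: np.random.Generator | None = None,
                 batch: int = 1, max_total: int | None = None) -> StrategyResult:
    """Apply one strategy to a dataset.

    ``rng`` supplies the escalation stream and is required for the ISS
    strategies; ``FC`` never enlarges the sample.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "FC":
        return _fc_result(d, detect_separation(d, classify=False).separated)
    if rng is None:
        raise ValueError("ISS strategies need an rng for the escalation stream")
    was_separated = detect_separation(d, classify=False).separated
    d2 = run_iss(d, sampler, rng, batch=batch, max_total=max_total)
    if strategy == "ML+ISS":
        fit = ml_fit(d2, check_separation=False)  # d2 is known non-separated
        return StrategyResult(strategy, fit, d.n, d2.n, was_separated)
    return _fc_result(d2, was_separated, "FC+ISS", n_original=d.n)


def run_all_strategies(d: Dataset, sampler: ScenarioSampler,
                       rng: np.random.Generator,
                       batch: int = 1, max_total: int | None = None
                       ) -> dict[str, StrategyResult]:
    """Run FC, ML+ISS and FC+ISS on one dataset with a shared ISS stream.

    The two ISS strategies are evaluated on the *same* escalated dataset, so
    within-replication contrasts are paired.  When the data are not separated
    to begin with, the Firth fit is shared between FC and FC+ISS.
    """
    sep = detect_separation(d, classify=False)
    fc = _fc_result(d, sep.separated)
    if not sep.separated:
        ml = ml_fit(d, check_separation=False)
        return {
            "FC": fc,
            "ML+ISS": StrategyResult("ML+ISS", ml, d.n, d.n, False),
            "FC+ISS": StrategyResult("FC+ISS", fc.fit, d.n, d.n, False),
        }
    d2 = _scan_until_clear(d, sep, sampler, rng, max_total or 100 * d.n) \
        if batch == 1 else run_iss(d, sampler, rng, batch=batch, max_total=max_total)
    ml = ml_fit(d2, check_separation=False)
    fc_iss = _fc_result(d2, True, "FC+ISS", n_original=d.n)
    return {
        "FC": fc,
        "ML+ISS": StrategyResult("ML+ISS", ml, d.n, d2.n, True),
        "FC+ISS": fc_iss,
    }
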