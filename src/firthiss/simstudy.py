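"""Factorial Monte-Carlo study of separation strategies.

The full design crosses K ∈ {2, 5, 10} covariates, N ∈ {80, 200, 500}
observations, marginal event rates E(Y) ∈ {0.1, 0.25} and target effects
β₁ ∈ {0, 0.35, 1.39, 2.77} — 72 scenarios.  Per replication a dataset is
generated, checked for separation, and analyzed by FC, ML+ISS and FC+ISS;
per scenario the study reports bias, MSE, coverage, rejection rate (type-I
error when β₁ = 0, power otherwise), mean CI width, the mean escalated
sample size N̄new, the prevalence of separation, and the cost-adjusted
relative efficiency

    CARE = (MSE_{ML+ISS} · N̄new) / (MSE_FC · N),

which weighs the efficiency gain of escalating the sample against its cost;
CARE > 1 favours Firth's correction on the original sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import ScenarioSampler
from .estimators import ConvergenceError
from .strategies import STRATEGIES, IssAbortError, run_all_strategies

__all__ = [
    "ScenarioConfig",
    "StrategySummary",
    "ScenarioMetrics",
    "full_grid",
    "run_scenario",
    "run_grid",
    "metrics_to_frame",
    "care",
    "aggregate",
    "coverage_plausible_interval",
]

K_LEVELS = (2, 5, 10)
N_LEVELS = (80, 200, 500)
RATE_LEVELS = (0.1, 0.25)
BETA1_LEVELS = (0.0, 0.35, 1.39, 2.77)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial design."""

    K: int
    N: int
    event_rate: float
    beta1: float
    n_reps: int = 1000
    master_seed: int = 0

    def rep_seed(self, rep: int) -> np.random.SeedSequence:
        """Deterministic per-replication seed, independent of run order."""
        key = (self.K, self.N, int(round(self.event_rate * 1000)),
               int(round(self.beta1 * 100)), rep)
        return np.random.SeedSequence(entropy=self.master_seed, spawn_key=key)


def full_grid(n_reps: int = 1000, master_seed: int = 0,
              n_reps_null: int | None = None) -> list[ScenarioConfig]:
    """All 72 scenario cells; null cells may use a different replication count."""
    out = []
    for rate in RATE_LEVELS:
        for K in K_LEVELS:
            for b1 in BETA1_LEVELS:
                for N in N_LEVELS:
                    reps = n_reps_null if (b1 == 0 and n_reps_null) else n_reps
                    out.append(ScenarioConfig(K, N, rate, b1, reps, master_seed))
    return out


@dataclass(frozen=True)
class StrategySummary:
    bias: float
    mse: float
    var: float
    coverage: float        # %
    rejection_rate: float  # %
    mean_ci_width: float
    mean_n_new: float


@dataclass(frozen=True)
class ScenarioMetrics:
    config: ScenarioConfig
    strategies: dict[str, StrategySummary]
    separation_prevalence: float  # %
    care: float
    n_excluded: int = 0
    n_unbounded_ci: int = 0
    exclusions: tuple = field(default_factory=tuple)


def care(mse_ml_iss: float, mean_n_new: float, mse_fc: float, n: float) -> float:
    """Cost-adjusted relative efficiency of ML+ISS versus FC.

    (MSE_{ML+ISS} · N̄new) / (MSE_FC · N); values above 1 mean Firth's
    correction at the original sample size is the more efficient use of
    observations.
    """
    for name, v in [("mse_ml_iss", mse_ml_iss), ("mean_n_new", mean_n_new),
                    ("mse_fc", mse_fc), ("n", n)]:
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (mse_ml_iss * mean_n_new) / (mse_fc * n)


def coverage_plausible_interval(nominal: float = 0.95,
                                n_reps: int = 1000) -> tuple[float, float]:
    """Interval into which the empirical coverage of an exact method falls
    with probability 0.99: nominal ± 2.57·sqrt(nominal·(1−nominal)/n_reps)."""
    if not 0.0 < nominal < 1.0:
        raise ValueError("nominal must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    half = 2.57 * np.sqrt(nominal * (1.0 - nominal) / n_reps)
    return (nominal - half, nominal + half)


def run_scenario(cfg: ScenarioConfig, sampler: ScenarioSampler | None = None,
                 n_calib: int = 10**6) -> ScenarioMetrics:
    """Run all replications of one scenario and aggregate the measures.

    Replications where a fit or the escalation aborts are excluded from the
    aggregates and counted (never silently dropped).  The estimand is the
    target coefficient β₁.
    """
    if sampler is None:
        sampler = ScenarioSampler(cfg.K, cfg.beta1, cfg.event_rate, n_calib=n_calib)
    est = {s: [] for s in STRATEGIES}
    lo = {s: [] for s in STRATEGIES}
    hi = {s: [] for s in STRATEGIES}
    n_new = {s: [] for s in STRATEGIES}
    separated: list[bool] = []
    exclusions: list[tuple[int, str]] = []
    n_unbounded = 0
    for rep in range(cfg.n_reps):
        rng = np.random.default_rng(cfg.rep_seed(rep))
        d = sampler.sample(cfg.N, rng)
        try:
            results = run_all_strategies(d, sampler, rng)
        except (IssAbortError, ConvergenceError) as exc:
            exclusions.append((rep, f"{type(exc).__name__}: {exc}"))
            continue
        separated.append(results["FC"].was_separated)
        for s in STRATEGIES:
            r = results[s]
            est[s].append(float(r.fit.beta[1]))
            lo[s].append(float(r.fit.ci_lower[1]))
            hi[s].append(float(r.fit.ci_upper[1]))
            n_new[s].append(r.n_new)
            n_unbounded += sum(1 for f in r.fit.ci_flags if "unbounded" in f)
    if not separated:
        raise RuntimeError("all replications of the scenario were excluded")
    summaries = {}
    for s in STRATEGIES:
        b = np.asarray(est[s])
        l, u = np.asarray(lo[s]), np.asarray(hi[s])
        bias = float(b.mean() - cfg.beta1)
        summaries[s] = StrategySummary(
            bias=bias,
            mse=float(np.mean((b - cfg.beta1) ** 2)),
            var=float(b.var()),
            coverage=100.0 * float(np.mean((l <= cfg.beta1) & (cfg.beta1 <= u))),
            rejection_rate=100.0 * float(np.mean((l > 0.0) | (u < 0.0))),
            mean_ci_width=float(np.mean(u - l)),
            mean_n_new=float(np.mean(n_new[s])),
        )
    prevalence = 100.0 * float(np.mean(separated))
    c = care(summaries["ML+ISS"].mse, summaries["ML+ISS"].mean_n_new,
             summaries["FC"].mse, cfg.N)
    return ScenarioMetrics(cfg, summaries, prevalence, c,
                           n_excluded=len(exclusions),
                           n_unbounded_ci=n_unbounded,
                           exclusions=tuple(exclusions))


def metrics_to_frame(metrics: list[ScenarioMetrics]) -> pd.DataFrame:
    """Tidy table: one row per scenario × strategy."""
    rows = []
    for m in metrics:
        for s, v in m.strategies.items():
            rows.append({
                "K": m.config.K, "N": m.config.N, "EY": m.config.event_rate,
                "beta1": m.config.beta1, "strategy": s,
                "bias": v.bias, "mse": v.mse, "coverage": v.coverage,
                "rejection_rate": v.rejection_rate, "width": v.mean_ci_width,
                "n_new_mean": v.mean_n_new, "sep_prev": m.separation_prevalence,
                "care": m.care, "n_excluded": m.n_excluded,
            })
    return pd.DataFrame(rows)


def run_grid(configs: list[ScenarioConfig], n_calib: int = 10**6,
             progress: bool = False) -> list[ScenarioMetrics]:
    """Run a list of scenarios sequentially (samplers cached per generating model)."""
    samplers: dict[tuple, ScenarioSampler] = {}
    out = []
    for i, cfg in enumerate(configs):
        key = (cfg.K, cfg.beta1, cfg.event_rate)
        if key not in samplers:
            samplers[key] = ScenarioSampler(cfg.K, cfg.beta1, cfg.event_rate,
                                            n_calib=n_calib)
        out.append(run_scenario(cfg, sampler=samplers[key]))
        if progress:
            print(f"[{i + 1}/{len(configs)}] K={cfg.K} N={cfg.N} "
                  f"EY={cfg.event_rate} beta1={cfg.beta1} done", flush=True)
    return out


def aggregate(df: pd.DataFrame, strategy: str | None = None,
              **filters) -> pd.Series:
    """Unweighted mean of each measure over the selected scenario cells.

    Filters are column=value (or column=list-of-values) predicates on the tidy
    frame, e.g. ``aggregate(df, strategy='FC', EY=0.25, beta1=0.0)``.
    Aggregation is over scenario cells, never pooled replications.
    """
    sel = df
    if strategy is not None:
        sel = sel[sel["strategy"] == strategy]
    for col, val in filters.items():
        if col not in sel.columns:
            raise KeyError(f"unknown column {col!r}")
        if isinstance(val, (list, tuple, set, np.ndarray)):
            sel = sel[sel[col].isin(list(val))]
        else:
            sel = sel[sel[col] == val]
    if sel.empty:
        raise ValueError("no scenarios match the given filters")
    return sel.drop(columns=["strategy"]).mean(numeric_only=True)
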