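"""Nested-loop ordering, aggregate summaries, and exports of study results.

Scenario cells are ordered for nested loop plots with the event rate E(Y) as
the outermost factor, then the number of covariates K, then the target effect
β₁, and the sample size N innermost, giving each cell a stable position 1..72.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .simstudy import (
    BETA1_LEVELS,
    K_LEVELS,
    N_LEVELS,
    RATE_LEVELS,
    aggregate,
    coverage_plausible_interval,
)

__all__ = ["order_scenarios", "summary_report", "nested_loop_plot"]

_FACTORS = ["EY", "K", "beta1", "N"]
_LEVELS = {"EY": RATE_LEVELS, "K": K_LEVELS, "beta1": BETA1_LEVELS, "N": N_LEVELS}


def order_scenarios(df: pd.DataFrame, require_complete: bool = True) -> pd.DataFrame:
    """Sort a tidy results frame into nested-loop order with a position index.

    Raises if the full factorial grid is incomplete (listing the absentees)
    unless ``require_complete`` is False.
    """
    cells = df[_FACTORS].drop_duplicates()
    if require_complete:
        expected = {(e, k, b, n) for e in RATE_LEVELS for k in K_LEVELS
                    for b in BETA1_LEVELS for n in N_LEVELS}
        present = {tuple(r) for r in cells.itertuples(index=False)}
        missing = sorted(expected - present)
        if missing:
            raise ValueError(f"incomplete scenario grid; missing cells: {missing}")
    out = df.copy()
    for f in _FACTORS:
        order = {v: i for i, v in enumerate(_LEVELS[f])}
        bad = set(out[f]) - set(order)
        if bad:
            raise ValueError(f"unexpected {f} levels: {sorted(bad)}")
        out[f"_o_{f}"] = out[f].map(order)
    out = out.sort_values([f"_o_{f}" for f in _FACTORS], kind="stable")
    key = out[_FACTORS].apply(tuple, axis=1)
    positions = {c: i + 1 for i, c in enumerate(dict.fromkeys(key))}
    out.insert(0, "position", key.map(positions))
    return out.drop(columns=[f"_o_{f}" for f in _FACTORS]).reset_index(drop=True)


def summary_report(df: pd.DataFrame, n_reps: int, nominal: float = 0.95) -> dict:
    """Aggregate the study the way the results are usually quoted.

    Per event-rate stratum and strategy: mean type-I error over the null
    cells, mean power over the non-null cells, mean coverage and CI width
    over all cells, a width variant excluding the (N=80, K=10) cells, and
    the count of cells whose coverage falls outside the plausible interval
    for ``n_reps`` replications.
    """
    lo, hi = coverage_plausible_interval(nominal, n_reps)
    strategies = sorted(df["strategy"].unique())
    report: dict = {
        "n_reps": n_reps,
        "plausible_coverage_interval": [lo, hi],
        "strata": {},
    }
    nonnull = [b for b in BETA1_LEVELS if b != 0]

    def _maybe(measure, **filters):
        try:
            return float(aggregate(df, **filters)[measure])
        except ValueError:  # stratum absent from a partial grid
            return None

    for rate in RATE_LEVELS:
        stratum: dict = {}
        for s in strategies:
            cells = df[(df["strategy"] == s) & (df["EY"] == rate)]
            if cells.empty:
                continue
            flagged = cells[(cells["coverage"] / 100 < lo) | (cells["coverage"] / 100 > hi)]
            no_edge = cells[~((cells["N"] == 80) & (cells["K"] == 10))]
            stratum[s] = {
                "mean_type1_error_pct": _maybe("rejection_rate", strategy=s,
                                               EY=rate, beta1=0.0),
                "mean_power_pct": _maybe("rejection_rate", strategy=s,
                                         EY=rate, beta1=nonnull),
                "mean_coverage_pct": float(cells["coverage"].mean()),
                "mean_ci_width": float(cells["width"].mean()),
                "mean_ci_width_excl_N80_K10": float(no_edge["width"].mean()),
                "n_coverage_outside_plausible": int(len(flagged)),
                "n_cells": int(len(cells)),
            }
        if stratum:
            report["strata"][f"EY={rate}"] = stratum
    mliss = df[df["strategy"] == "ML+ISS"]
    ratios = mliss["n_new_mean"] / mliss["N"]
    idx = ratios.idxmax()
    report["max_n_new_ratio"] = float(ratios.max())
    report["max_n_new_ratio_cell"] = {
        c: (float(mliss.loc[idx, c]) if c != "K" else int(mliss.loc[idx, c]))
        for c in ("K", "N", "EY", "beta1")
    }
    return report


def write_summary(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def nested_loop_plot(ordered: pd.DataFrame, value: str, path=None, ax=None):
    """Minimal nested loop plot of one measure over the ordered scenarios.

    Purely cosmetic convenience; all analysis consumes the ordered table.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    for s, grp in ordered.groupby("strategy"):
        ax.step(grp["position"], grp[value], where="mid", label=s)
    ax.set_xlabel("scenario position (E(Y) ▸ K ▸ β1 ▸ N)")
    ax.set_ylabel(value)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
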