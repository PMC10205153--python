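"""Sequential Bayes-factor stopping rule and simulation-based design analysis.

Recruitment (or here, inclusion of simulated subjects) continues until the
Bayes factor reaches the evidence threshold in either direction or a
participant cap is hit. Threshold comparisons are inclusive (BF >= 10
stops for H1, BF <= 1/10 for H0; 'reaching' the threshold counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evidence import bayes_factor_for_term
from .model import ModelSpec
from .simulate import TruthParams, simulate_trial_table

__all__ = [
    "SequentialTrace",
    "DesignCurve",
    "apply_stopping_rule",
    "sequential_bf_trace",
    "design_analysis",
]


@dataclass
class SequentialTrace:
    points: list[tuple[int, float]]  # ordered (n_subjects, BF10)
    decision: str  # stop_H1 | stop_H0 | cap_reached
    decision_n: int


@dataclass
class DesignCurve:
    table: pd.DataFrame  # n, rep, bf10 (NaN for failed reps)
    summaries: pd.DataFrame  # per-n median BF and decision fractions
    n_failed: int


def apply_stopping_rule(
    points: list[tuple[int, float]], threshold: float = 10.0, cap: int = 150
) -> tuple[str, int]:
    """Earliest crossing wins; no crossing by the cap -> cap_reached."""
    if not points:
        raise ValueError("empty trace")
    for n, bf in sorted(points):
        if n > cap:
            break
        if bf >= threshold:
            return "stop_H1", n
        if bf <= 1.0 / threshold:
            return "stop_H0", n
    last_n = min(max(n for n, _ in points), cap)
    return "cap_reached", last_n


def sequential_bf_trace(
    table: pd.DataFrame,
    spec: ModelSpec,
    term: str,
    eval_points,
    seed: int = 0,
    threshold: float = 10.0,
    cap: int = 150,
    *,
    fit_kwargs: dict | None = None,
    subject_order=None,
) -> SequentialTrace:
    """Refit the full/null pair on the first n subjects at each evaluation
    point and apply the stopping rule to the resulting BF trace."""
    eval_points = list(eval_points)
    if any(b > a for a, b in zip(eval_points[1:], eval_points)):
        raise ValueError("eval_points must be increasing")
    subjects = (
        list(subject_order)
        if subject_order is not None
        else sorted(table[spec.subject_col].unique())
    )
    points = []
    for k, n in enumerate(eval_points):
        if n > len(subjects):
            warnings.warn(
                f"evaluation point {n} exceeds available subjects ({len(subjects)}); truncating"
            )
            break
        sub = table[table[spec.subject_col].isin(subjects[:n])]
        out = bayes_factor_for_term(
            sub, spec, term, seed=seed + 1000 * k, fit_kwargs=fit_kwargs
        )
        points.append((n, out["bf10"]))
        decision, decision_n = apply_stopping_rule(points, threshold, cap)
        if decision != "cap_reached":
            return SequentialTrace(points, decision, decision_n)
    decision, decision_n = apply_stopping_rule(points, threshold, cap)
    return SequentialTrace(points, decision, decision_n)


def design_analysis(
    truth: TruthParams,
    n_grid,
    n_items: int,
    reps: int,
    spec: ModelSpec,
    term: str,
    seed: int = 0,
    threshold: float = 10.0,
    *,
    fit_kwargs: dict | None = None,
) -> DesignCurve:
    """Simulate-fit-bridge at each grid sample size; summarize BF10 per n.

    Each (n, rep) cell generates a fresh data set from ``truth`` via the
    synthetic-data generators, fits the full and null models, and records
    BF10. Failed fits are excluded from summaries and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    n_failed = 0
    ss = np.random.SeedSequence(seed)
    cells = [(int(n), r) for n in n_grid for r in range(reps)]
    children = ss.spawn(len(cells))
    for (n, r), child in zip(cells, children):
        s = int(child.generate_state(1)[0]) % (2**31)
        try:
            _, _, table = simulate_trial_table(truth, n, n_items, seed=s)
            out = bayes_factor_for_term(table, spec, term, seed=s, fit_kwargs=fit_kwargs)
            rows.append({"n": n, "rep": r, "bf10": out["bf10"]})
        except Exception as exc:  # noqa: BLE001 - failed reps are reported, not fatal
            warnings.warn(f"design-analysis rep (n={n}, rep={r}) failed: {exc}")
            n_failed += 1
            rows.append({"n": n, "rep": r, "bf10": np.nan})
    tab = pd.DataFrame(rows)
    summaries = (
        tab.dropna()
        .groupby("n")["bf10"]
        .agg(
            median_bf10="median",
            frac_stop_h1=lambda v: float(np.mean(v >= threshold)),
            frac_stop_h0=lambda v: float(np.mean(v <= 1 / threshold)),
            n_reps="count",
        )
        .reset_index()
    )
    return DesignCurve(table=tab, summaries=summaries, n_failed=n_failed)
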