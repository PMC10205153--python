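"""Cloze-test predictor construction.

Turns raw cloze completions into the continuous predictors used by the
amplitude models: the target word's cloze proportion, its additively
smoothed log2 cloze probability, the Shannon entropy (bits) of the full
completion distribution, and centred versions of both.

Conventions
-----------
* All logarithms are base 2; entropy is reported in bits.
* Additive (Laplace) smoothing of the target probability uses a
  two-outcome convention, ``(k + 1) / (n + 2)``, which keeps the smoothed
  probability strictly inside (0, 1).
* Centring is always performed over exactly the rows entering a given
  model, not over the full item set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClozeResponseSet",
    "collapse_responses",
    "cloze_probability",
    "smoothed_log2_cloze",
    "entropy_bits",
    "center_predictor",
    "build_predictor_table",
    "read_responses_tsv",
    "read_targets_tsv",
]

CONDITION_LABELS = ("a", "b", "c", "d")


@dataclass
class ClozeResponseSet:
    """Stem-collapsed cloze completions for one item x condition cell."""

    item_id: str
    condition_label: str
    responses: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("no responses")

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(self.responses))

    def probabilities(self) -> np.ndarray:
        c = np.array(sorted(self.counts.values()), dtype=float)
        return c / c.sum()


def collapse_responses(
    raw_tokens: Sequence[str],
    stem_map: Mapping[str, str] | None = None,
    *,
    item_id: str = "",
    condition_label: str = "",
) -> ClozeResponseSet:
    """Lowercase, drop blanks, and collapse tokens onto their stems.

    ``stem_map`` maps a lowercase token to its stem; unmapped tokens map to
    themselves. Blank/whitespace-only tokens are treated as omissions and
    dropped before the respondent count is formed.
    """
    if stem_map is None:
        stem_map = {}
    tokens = [t.strip().lower() for t in raw_tokens]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise ValueError("no responses")
    stems = [stem_map.get(t, t) for t in tokens]
    return ClozeResponseSet(item_id=item_id, condition_label=condition_label, responses=stems)


def cloze_probability(counts: Mapping[str, int], target: str, n: int) -> float:
    """Proportion of respondents producing ``target`` (0 if absent)."""
    if n <= 0:
        raise ValueError("n must be positive")
    total = sum(counts.values())
    if total != n:
        raise ValueError(f"counts sum to {total}, expected n={n}")
    return counts.get(target, 0) / n


def smoothed_log2_cloze(k_target: int, n: int) -> float:
    """log2 of the Laplace-smoothed target probability, (k+1)/(n+2).

    Strictly negative for all valid inputs and monotone increasing in
    ``k_target``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k_target < 0 or k_target > n:
        raise ValueError(f"k_target={k_target} outside [0, n={n}]")
    return math.log2((k_target + 1) / (n + 2))


def entropy_bits(probabilities: Iterable[float], *, atol: float = 1e-8) -> float:
    """Shannon entropy in bits, -sum(p * log2 p); zero terms contribute 0."""
    p = np.asarray(list(probabilities), dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def center_predictor(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Subtract the mean of ``values`` (mean over exactly these rows)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot centre an empty vector")
    return v - v.mean()


def build_predictor_table(
    response_sets: Sequence[ClozeResponseSet],
    targets: Mapping[tuple[str, str], str],
    *,
    center: bool = True,
) -> pd.DataFrame:
    """Assemble the per item x condition predictor table.

    Parameters
    ----------
    response_sets
        One :class:`ClozeResponseSet` per (item, condition) cell.
    targets
        Mapping ``(item_id, condition_label) -> target stem``.
    center
        If True, append ``entropy_centered`` / ``log2_cloze_centered``
        columns centred over the emitted rows.
    """
    rows = []
    for rs in response_sets:
        key = (rs.item_id, rs.condition_label)
        if key not in targets:
            raise KeyError(f"no target word for item={rs.item_id} condition={rs.condition_label}")
        target = targets[key].strip().lower()
        counts = rs.counts
        n = rs.n_respondents
        k = counts.get(target, 0)
        rows.append(
            {
                "item_id": rs.item_id,
                "condition": rs.condition_label,
                "target_token": target,
                "n_respondents": n,
                "k_target": k,
                "proportion_target": cloze_probability(counts, target, n),
                "log2_cloze_smoothed": smoothed_log2_cloze(k, n),
                "entropy_bits": entropy_bits(rs.probabilities()),
            }
        )
    table = pd.DataFrame(rows)
    if center and len(table):
        table["entropy_centered"] = center_predictor(table["entropy_bits"].to_numpy())
        table["log2_cloze_centered"] = center_predictor(table["log2_cloze_smoothed"].to_numpy())
    return table


def read_responses_tsv(path) -> list[ClozeResponseSet]:
    """Read raw responses (item_id, condition, respondent_id, response_token)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"item_id", "condition", "respondent_id", "response_token"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"responses TSV missing columns: {sorted(missing)}")
    sets = []
    for (item, cond), grp in df.groupby(["item_id", "condition"], sort=True):
        sets.append(
            collapse_responses(
                grp["response_token"].fillna("").tolist(),
                item_id=str(item),
                condition_label=str(cond),
            )
        )
    return sets


def read_targets_tsv(path) -> dict[tuple[str, str], str]:
    """Read target words (item_id, condition, target_token)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"item_id", "condition", "target_token"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"targets TSV missing columns: {sorted(missing)}")
    return {(r.item_id, r.condition): r.target_token for r in df.itertuples()}
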