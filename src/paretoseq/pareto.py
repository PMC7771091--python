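"""Non-dominated sorting of genes over signed Z-score objectives.

Each gene carries one Z score per histone mark.  The objective vector is
(alpha_1 Z_1, ..., alpha_n Z_n) with alpha = +1 for activating and -1 for
repressive marks, and every component is maximized: a gene whose
expression and activating marks move together, and whose repressive marks
move opposite to expression, scores high in every component.

Gene a *dominates* gene b when a's objective vector is >= b's in every
component and > in at least one.  Front 1 is the set of non-dominated
genes; successive fronts are obtained by removing the current front and
repeating ("peeling").  Identical vectors never dominate each other and
share a front.

``assign_fronts`` peels on a vectorized pairwise dominance matrix;
``brute_force_fronts`` is a deliberately naive pure-Python re-derivation
kept as an independent test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chip import ACTIVATING, REPRESSIVE
from .errors import ValidationError
from .integration import ZScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "ParetoRanking",
    "dominates",
    "signed_objectives",
    "assign_fronts",
    "brute_force_fronts",
]


@dataclass
class ParetoRanking:
    """Ranking table: one row per gene with its raw Z vector and front index.

    Rows are ordered by ascending front, then gene id; front indices are
    contiguous starting at 1.
    """

    table: pd.DataFrame  # index gene_id; columns: <marks...>, front

    def __post_init__(self) -> None:
        if "front" not in self.table.columns:
            raise ValidationError("ranking table lacks a 'front' column")
        fronts = np.sort(self.table["front"].unique())
        if len(fronts) and not np.array_equal(fronts, np.arange(1, len(fronts) + 1)):
            raise ValidationError(f"front indices not contiguous from 1: {fronts}")

    @property
    def marks(self) -> list[str]:
        return [c for c in self.table.columns if c != "front"]

    def front(self, i: int) -> list[str]:
        return list(self.table.index[self.table["front"] == i])

    def n_fronts(self) -> int:
        return int(self.table["front"].max())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ParetoRanking":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff a >= b componentwise with strict > in at least one component."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"objective length mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def signed_objectives(zt: ZScoreTable) -> pd.DataFrame:
    """Apply alpha in {+1, -1} per mark so every objective is maximized.

    The single place where mark direction touches the Z values: repressive
    marks are negated, activating marks pass through.
    """
    signs = {}
    for mark in zt.zscores.columns:
        d = zt.directions[mark]
        if d == ACTIVATING:
            signs[mark] = 1.0
        elif d == REPRESSIVE:
            signs[mark] = -1.0
        else:
            raise ValidationError(f"mark {mark}: unknown direction {d!r}")
    return zt.zscores * pd.Series(signs)


def _peel_fronts(values: np.ndarray) -> np.ndarray:
    """Front index (1-based) for each row of ``values``, all columns maximized."""
    n = len(values)
    # full pairwise dominance matrix: dom[i, j] == row i dominates row j
    ge = (values[:, None, :] >= values[None, :, :]).all(axis=2)
    dom = ge & ~ge.T  # a>=b everywhere and not b>=a everywhere  <=>  a dominates b
    fronts = np.zeros(n, dtype=np.int64)
    remaining = np.ones(n, dtype=bool)
    level = 0
    while remaining.any():
        level += 1
        sub = dom[np.ix_(remaining, remaining)]
        nondominated = ~sub.any(axis=0)
        idx = np.flatnonzero(remaining)[nondominated]
        fronts[idx] = level
        remaining[idx] = False
    return fronts


def _ranking_from_fronts(zt: ZScoreTable, fronts: np.ndarray) -> ParetoRanking:
    table = zt.zscores.copy()
    table["front"] = fronts
    # ascending front, then gene id within each front
    table = table.sort_index(kind="stable").sort_values("front", kind="stable")
    return ParetoRanking(table)


def assign_fronts(zt: ZScoreTable) -> ParetoRanking:
    """Partition all genes into Pareto fronts over the signed objectives."""
    if zt.zscores.empty:
        raise ValidationError("assign_fronts: empty Z-score table")
    values = signed_objectives(zt).to_numpy(dtype=float)
    return _ranking_from_fronts(zt, _peel_fronts(values))


def brute_force_fronts(zt: ZScoreTable) -> ParetoRanking:
    """O(n^2 k) reference implementation: repeated exhaustive pairwise peeling.

    Independent of :func:`assign_fronts` — re-checks dominance with the
    scalar :func:`dominates` predicate inside explicit Python loops each
    round.  Kept for equivalence testing only.
    """
    if zt.zscores.empty:
        raise ValidationError("brute_force_fronts: empty Z-score table")
    values = [tuple(row) for row in signed_objectives(zt).to_numpy(dtype=float)]

    def _dom(a: tuple, b: tuple) -> bool:
        strict = False
        for x, y in zip(a, b):
            if x < y:
                return False
            if x > y:
                strict = True
        return strict

    n = len(values)
    fronts = [0] * n
    remaining = set(range(n))
    level = 0
    while remaining:
        level += 1
        current = [
            i
            for i in remaining
            if not any(_dom(values[j], values[i]) for j in remaining if j != i)
        ]
        for i in current:
            fronts[i] = level
            remaining.discard(i)
    return _ranking_from_fronts(zt, np.array(fronts, dtype=np.int64))
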