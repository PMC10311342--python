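"""Exact integer/rational helpers shared by the dynamic programs.

All statistics in this package live in exact arithmetic: branch lengths are
rationals, subset counts are arbitrary-precision integers, and the DP tables
never round.  This module provides the Pascal-triangle binomial table the
moment recurrences consume, plus the common-denominator scaling used to run
the DP loops in plain Python integers.
"""

from __future__ import annotations

from fractions import Fraction
from math import lcm
from typing import Sequence

__all__ = ["BinomialTable", "binomial_table", "integerize_lengths"]


class BinomialTable:
    """Exact binomial coefficients C(i, j) for 0 <= i <= n, 0 <= j <= k_max.

    Built row by row as a Pascal triangle (C(i,j) = C(i-1,j-1) + C(i-1,j)).
    Lookups with j < 0 or j > i return 0 — the convention under which the
    boundary cases of the per-clade recurrences collapse automatically when a
    subset size exceeds a child clade's leaf count.
    """

    __slots__ = ("n", "k_max", "_rows")

    def __init__(self, n: int, k_max: int):
        if n < 0:
            raise ValueError("n must be non-negative")
        if not 0 <= k_max <= n:
            raise ValueError("k_max must satisfy 0 <= k_max <= n")
        self.n = n
        self.k_max = k_max
        rows: list[list[int]] = []
        for i in range(n + 1):
            width = min(i, k_max) + 1
            row = [1] * width
            if i > 0:
                prev = rows[i - 1]
                for j in range(1, width):
                    left = prev[j - 1]
                    right = prev[j] if j < len(prev) else 0
                    row[j] = left + right
            rows.append(row)
        self._rows = rows

    def __call__(self, i: int, j: int) -> int:
        if j < 0 or j > i:
            return 0
        if i > self.n or j > self.k_max:
            raise IndexError(
                f"C({i},{j}) outside the precomputed range (n={self.n}, "
                f"k_max={self.k_max})"
            )
        return self._rows[i][j]


def binomial_table(n: int, k_max: int) -> BinomialTable:
    """Precompute C(i, j) for i <= n, j <= k_max via a Pascal triangle."""
    return BinomialTable(n, k_max)


def integerize_lengths(
    lengths: Sequence[Fraction | None],
) -> tuple[list[int], int]:
    """Scale rational branch lengths to integers by their denominator LCM.

    Returns ``(scaled, L)`` with ``scaled[v] = lengths[v] * L`` as an int
    (0 where the input is None, i.e. the root).  Running the DP tables on the
    scaled integers and dividing by L (or L**2 for second moments) at readout
    is exact and avoids per-operation rational normalization.
    """
    L = 1
    for w in lengths:
        if w is not None:
            L = lcm(L, w.denominator)
    scaled = [0 if w is None else int(w * L) for w in lengths]
    return scaled, L
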