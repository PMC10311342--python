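"""Per-clade minimum and maximum PD over all size-k subsets, in O(kn).

For every internal node v with children x and y, a size-i subset of T_v's
leaves splits as r taxa under x and l = i - r under y.  Writing w_x, w_y for
the two child-edge weights, the optimal PD satisfies

    opt(v, i) = opt over r of  opt(x, r) + w_x * [r >= 1]
                             + opt(y, l) + w_y * [l >= 1]

with opt(leaf, i) = 0 and the sentinel opt(., 0) = 0.  The single loop over
r in [max(0, i - |y|), min(|x|, i)] covers the three cases (all taxa under x,
all under y, or split) at once.  Summed over all nodes, the number of (r, l)
pairs visited is O(kn), which `pair_count` reports exactly as a
hardware-independent complexity diagnostic.

Minimum and maximum tables are filled simultaneously in one pass; optimal
subsets are recovered by backtracking.
"""

from __future__ import annotations

from fractions import Fraction

from .exact import integerize_lengths
from .pd import TaxonSubset
from .tree import PhyloTree

__all__ = [
    "MinMaxTable",
    "min_max_pd_tables",
    "min_pd_table",
    "max_pd_table",
    "backtrack_set",
    "pair_count",
]


class MinMaxTable:
    """Per-clade tables of minimum (δ) and maximum (Δ) PD.

    Entries exist for every clade v and every subset size 1 <= ki <=
    min(k, |v|); sizes beyond |v| are undefined and raise.  Values are exact
    rationals.
    """

    __slots__ = ("tree", "k", "_scale", "_wint", "_dmin", "_dmax")

    def __init__(self, tree: PhyloTree, k: int, scale: int, wint: list[int],
                 dmin: list[list[int]], dmax: list[list[int]]):
        self.tree = tree
        self.k = k
        self._scale = scale
        self._wint = wint
        self._dmin = dmin
        self._dmax = dmax

    def _check(self, v: int, ki: int) -> None:
        size = self.tree.clade_size(v)
        if ki > size:
            raise ValueError(f"PD statistics undefined for ki={ki} > |v|={size}")
        if not 1 <= ki <= self.k:
            raise ValueError(f"ki={ki} outside the computed range 1..{self.k}")

    def min_pd(self, v, ki: int) -> Fraction:
        """δ(v, ki): minimum PD over all size-ki subsets of the clade."""
        v = self.tree.find_clade(v)
        self._check(v, ki)
        return Fraction(self._dmin[v][ki], self._scale)

    def max_pd(self, v, ki: int) -> Fraction:
        """Δ(v, ki): maximum PD over all size-ki subsets of the clade."""
        v = self.tree.find_clade(v)
        self._check(v, ki)
        return Fraction(self._dmax[v][ki], self._scale)


def _loop_bounds(i: int, nx: int, ny: int) -> range:
    return range(max(0, i - ny), min(nx, i) + 1)


def min_max_pd_tables(tree: PhyloTree, k: int) -> MinMaxTable:
    """Compute δ(v, ki) and Δ(v, ki) for every clade and 1 <= ki <= min(k, |v|).

    Single post-order pass; both objectives share the loop structure.  Time
    and space O(kn).
    """
    tree.require_binary()
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")
    wint, scale = integerize_lengths(tree.length)
    dmin: list[list[int]] = [None] * tree.n_nodes  # type: ignore[list-item]
    dmax: list[list[int]] = [None] * tree.n_nodes  # type: ignore[list-item]
    for v in tree.postorder():
        if tree.is_leaf(v):
            dmin[v] = [0, 0]  # sentinel ki=0 and ki=1
            dmax[v] = [0, 0]
            continue
        x, y = tree.children[v]
        nx, ny = tree.clade_size(x), tree.clade_size(y)
        wx, wy = wint[x], wint[y]
        m = min(k, nx + ny)
        row_min = [0] * (m + 1)
        row_max = [0] * (m + 1)
        mnx, mny = dmin[x], dmin[y]
        mxx, mxy = dmax[x], dmax[y]
        for i in range(1, m + 1):
            best_min = None
            best_max = None
            for r in _loop_bounds(i, nx, ny):
                l = i - r
                add = (wx if r >= 1 else 0) + (wy if l >= 1 else 0)
                lo = mnx[r] + mny[l] + add
                hi = mxx[r] + mxy[l] + add
                if best_min is None or lo < best_min:
                    best_min = lo
                if best_max is None or hi > best_max:
                    best_max = hi
            row_min[i] = best_min
            row_max[i] = best_max
        dmin[v] = row_min
        dmax[v] = row_max
    return MinMaxTable(tree, k, scale, wint, dmin, dmax)


def min_pd_table(tree: PhyloTree, k: int) -> MinMaxTable:
    """Per-clade minimum-PD table (the maximum table comes along for free)."""
    return min_max_pd_tables(tree, k)


def max_pd_table(tree: PhyloTree, k: int) -> MinMaxTable:
    """Per-clade maximum-PD table (same single-pass computation)."""
    return min_max_pd_tables(tree, k)


def backtrack_set(
    tree: PhyloTree,
    table: MinMaxTable,
    v,
    ki: int,
    objective: str = "min",
) -> TaxonSubset:
    """Recover a size-ki subset attaining δ(v, ki) or Δ(v, ki).

    Ties are broken deterministically toward the smallest r (fewest taxa from
    the left child).  O(n + k) time given the table.
    """
    if table.tree is not tree:
        raise ValueError("table was computed for a different tree")
    if objective not in ("min", "max"):
        raise ValueError("objective must be 'min' or 'max'")
    rows = table._dmin if objective == "min" else table._dmax
    v = tree.find_clade(v)
    table._check(v, ki)
    wint = table._wint
    labels: list[str] = []
    stack = [(v, ki)]
    while stack:
        u, i = stack.pop()
        if i == 0:
            continue
        if tree.is_leaf(u):
            labels.append(tree.label[u])
            continue
        x, y = tree.children[u]
        nx, ny = tree.clade_size(x), tree.clade_size(y)
        target = rows[u][i]
        for r in _loop_bounds(i, nx, ny):
            l = i - r
            val = (
                rows[x][r] + (wint[x] if r >= 1 else 0)
                + rows[y][l] + (wint[y] if l >= 1 else 0)
            )
            if val == target:
                stack.append((x, r))
                stack.append((y, l))
                break
        else:  # pragma: no cover - table/tree mismatch
            raise RuntimeError("backtracking failed; inconsistent table")
    return TaxonSubset(frozenset(labels), clade=v)


def pair_count(tree: PhyloTree, k: int) -> int:
    """I(T): exact number of (r, l) child-split pairs the DP loop visits.

    At each internal node v with children x, y this counts pairs with
    0 <= r <= |x|, 0 <= l <= |y| and r + l <= min(k, |v|); leaves contribute
    0.  I(T) is O(kn), so I(T)/(kn) staying bounded is a machine-independent
    witness of the algorithm's linear scaling in k*n.
    """
    tree.require_binary()
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")
    total = 0
    for v in tree.postorder():
        if tree.is_leaf(v):
            continue
        x, y = tree.children[v]
        nx, ny = tree.clade_size(x), tree.clade_size(y)
        m = min(k, nx + ny)
        for r in range(0, min(nx, m) + 1):
            total += min(ny, m - r) + 1
    return total
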