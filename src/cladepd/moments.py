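"""Exact average and variance of PD over all size-k subsets, per clade.

Let v^k be the collection of size-k leaf subsets of the clade at v, and write

    beta(v, k)  = sum of PD over v^k          (unnormalized first moment)
    alpha(v, k) = beta / C(|v|, k)            (mean PD of a uniform subset)
    gamma(v, k) = sum of PD^2 over v^k        (unnormalized second moment)
    psi(v, k)   = gamma / C(|v|, k) - alpha^2 (population variance)

Both sums satisfy post-order recurrences over the split (r taxa under the
left child x, l = k - r under the right child y).  With lam = w_x + w_y and
C(., .) the exact binomial table:

    beta(v,k) = sum_{r+l=k, 1<=r<=|x|, 1<=l<=|y|}
                    C(|y|,l) beta(x,r) + C(|x|,r) beta(y,l)
                  + C(|x|,r) C(|y|,l) lam
              + beta(x,k) + C(|x|,k) w_x
              + beta(y,k) + C(|y|,k) w_y

    gamma(v,k) = sum_{r+l=k, 1<=r<=|x|, 1<=l<=|y|}
                    C(|y|,l) gamma(x,r) + C(|x|,r) gamma(y,l)
                  + C(|x|,r) C(|y|,l) lam^2
                  + 2 [ beta(x,r) beta(y,l)
                        + lam (C(|y|,l) beta(x,r) + C(|x|,r) beta(y,l)) ]
               + gamma(x,k) + C(|x|,k) w_x^2 + 2 w_x beta(x,k)
               + gamma(y,k) + C(|y|,k) w_y^2 + 2 w_y beta(y,k)

with beta = gamma = 0 at leaves.  The two closed terms are the all-under-x /
all-under-y cases; out-of-range binomials evaluate to 0, so they vanish
automatically when k exceeds a child's leaf count.  Everything is exact:
weights are scaled to integers by their denominator LCM, the tables are big
integers, and alpha/psi are formed as rationals at readout.

A float mode (``exact=False``) runs the same recurrences in IEEE doubles for
very large n*k; it is approximate and never used by the test suite.
"""

from __future__ import annotations

from fractions import Fraction

from .exact import BinomialTable, binomial_table, integerize_lengths
from .tree import PhyloTree

__all__ = [
    "MomentTable",
    "moment_tables",
    "sum_pd_table",
    "avg_pd_table",
    "sumsq_pd_table",
    "var_pd_table",
]


class MomentTable:
    """Per-clade tables of beta, alpha, gamma, psi.

    Entries exist for every clade v and 1 <= ki <= min(k, |v|).  In exact
    mode all four accessors return :class:`fractions.Fraction`.
    """

    __slots__ = ("tree", "k", "binom", "exact", "_scale", "_beta", "_gamma")

    def __init__(self, tree: PhyloTree, k: int, binom: BinomialTable,
                 exact: bool, scale: int,
                 beta: list[list], gamma: list[list]):
        self.tree = tree
        self.k = k
        self.binom = binom
        self.exact = exact
        self._scale = scale
        self._beta = beta
        self._gamma = gamma

    def _check(self, v: int, ki: int) -> None:
        size = self.tree.clade_size(v)
        if ki > size:
            raise ValueError(f"PD statistics undefined for ki={ki} > |v|={size}")
        if not 1 <= ki <= self.k:
            raise ValueError(f"ki={ki} outside the computed range 1..{self.k}")

    def sum_pd(self, v, ki: int):
        """beta(v, ki): sum of PD over all size-ki subsets of the clade."""
        v = self.tree.find_clade(v)
        self._check(v, ki)
        raw = self._beta[v][ki]
        return Fraction(raw, self._scale) if self.exact else raw / self._scale

    def avg_pd(self, v, ki: int):
        """alpha(v, ki): mean PD of a uniformly random size-ki subset."""
        v = self.tree.find_clade(v)
        self._check(v, ki)
        count = self.binom(self.tree.clade_size(v), ki)
        raw = self._beta[v][ki]
        if self.exact:
            return Fraction(raw, count * self._scale)
        return raw / (count * self._scale)

    def sumsq_pd(self, v, ki: int):
        """gamma(v, ki): sum of squared PD over all size-ki subsets."""
        v = self.tree.find_clade(v)
        self._check(v, ki)
        raw = self._gamma[v][ki]
        sq = self._scale * self._scale
        return Fraction(raw, sq) if self.exact else raw / sq

    def var_pd(self, v, ki: int):
        """psi(v, ki): population variance of PD over size-ki subsets."""
        v = self.tree.find_clade(v)
        self._check(v, ki)
        count = self.binom(self.tree.clade_size(v), ki)
        mean = self.avg_pd(v, ki)
        raw = self._gamma[v][ki]
        if self.exact:
            return Fraction(raw, count * self._scale * self._scale) - mean * mean
        return raw / (count * self._scale * self._scale) - mean * mean


def moment_tables(
    tree: PhyloTree,
    k: int,
    binom: BinomialTable | None = None,
    exact: bool = True,
) -> MomentTable:
    """Compute beta, alpha, gamma, psi for every clade and 1 <= ki <= min(k, |v|).

    Parameters
    ----------
    tree : PhyloTree
        Full binary tree with rational branch lengths.
    k : int
        Maximum subset size, 1 <= k <= n.
    binom : BinomialTable, optional
        Precomputed Pascal triangle covering (n, k); built if absent.
    exact : bool
        Exact big-integer arithmetic (default).  ``False`` switches the
        recurrences to floats — approximate, for very large n*k only.
    """
    tree.require_binary()
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")
    if binom is None:
        binom = binomial_table(n, k)
    if binom.n < n or binom.k_max < k:
        raise ValueError("binomial table does not cover (n, k)")

    if exact:
        wint, scale = integerize_lengths(tree.length)
    else:
        wint = [0.0 if w is None else float(w) for w in tree.length]
        scale = 1

    zero = 0 if exact else 0.0
    beta: list[list] = [None] * tree.n_nodes  # type: ignore[list-item]
    gamma: list[list] = [None] * tree.n_nodes  # type: ignore[list-item]
    C = binom
    for v in tree.postorder():
        if tree.is_leaf(v):
            beta[v] = [zero, zero]
            gamma[v] = [zero, zero]
            continue
        x, y = tree.children[v]
        nx, ny = tree.clade_size(x), tree.clade_size(y)
        wx, wy = wint[x], wint[y]
        lam = wx + wy
        lam2 = lam * lam
        bx, by = beta[x], beta[y]
        gx, gy = gamma[x], gamma[y]
        m = min(k, nx + ny)
        row_b = [zero] * (m + 1)
        row_g = [zero] * (m + 1)
        for i in range(1, m + 1):
            # Cases I/II: all i taxa under one child (vanish when i > child size)
            if i <= nx:
                cxi = C(nx, i)
                b = bx[i] + cxi * wx
                g = gx[i] + cxi * wx * wx + 2 * wx * bx[i]
            else:
                b = zero
                g = zero
            if i <= ny:
                cyi = C(ny, i)
                b += by[i] + cyi * wy
                g += gy[i] + cyi * wy * wy + 2 * wy * by[i]
            # Case III: split r >= 1 under x, l = i - r >= 1 under y
            for r in range(max(1, i - ny), min(nx, i - 1) + 1):
                l = i - r
                cx = C(nx, r)
                cy = C(ny, l)
                bxr = bx[r]
                byl = by[l]
                b += cy * bxr + cx * byl + cx * cy * lam
                g += (
                    cy * gx[r] + cx * gy[l] + cx * cy * lam2
                    + 2 * (bxr * byl + lam * (cy * bxr + cx * byl))
                )
            row_b[i] = b
            row_g[i] = g
        beta[v] = row_b
        gamma[v] = row_g
    return MomentTable(tree, k, binom, exact, scale, beta, gamma)


def sum_pd_table(tree: PhyloTree, k: int, binom=None, exact=True) -> MomentTable:
    """Per-clade beta table (all four moments come from the same pass)."""
    return moment_tables(tree, k, binom, exact)


def avg_pd_table(tree: PhyloTree, k: int, binom=None, exact=True) -> MomentTable:
    """Per-clade alpha table."""
    return moment_tables(tree, k, binom, exact)


def sumsq_pd_table(tree: PhyloTree, k: int, binom=None, exact=True) -> MomentTable:
    """Per-clade gamma table."""
    return moment_tables(tree, k, binom, exact)


def var_pd_table(tree: PhyloTree, k: int, binom=None, exact=True) -> MomentTable:
    """Per-clade psi table."""
    return moment_tables(tree, k, binom, exact)
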