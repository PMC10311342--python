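"""Brute-force reference implementation by explicit subset enumeration.

Ground truth for the dynamic programs on small instances: enumerate every
size-k leaf subset of a clade, evaluate each PD exactly, and summarize the
resulting multiset.  Exponential by design (the cap guards against misuse);
the DPs must agree with these numbers exactly, not approximately.

`pd_by_edge_marking` is a second, independent route to PD (sum over edges of
weight times an indicator that the subset hits the clade below the edge),
used to cross-check :func:`cladepd.pd.pd_of_subset` itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import NamedTuple

from .exact import binomial_table
from .pd import pd_of_subset
from .tree import PhyloTree

__all__ = ["PDDistribution", "OracleStats", "enumerate_pd", "oracle_stats",
           "pd_by_edge_marking"]


@dataclass(frozen=True)
class PDDistribution:
    """The full multiset of PD values over all size-ki subsets of a clade."""

    clade: int
    ki: int
    values: tuple[Fraction, ...]

    def __len__(self) -> int:
        return len(self.values)


class OracleStats(NamedTuple):
    min: Fraction
    max: Fraction
    mean: Fraction
    variance: Fraction  # population variance


def enumerate_pd(
    tree: PhyloTree,
    clade=None,
    ki: int = 1,
    cap: int = 10**6,
) -> PDDistribution:
    """Enumerate PD over every size-ki subset of the clade, in lexicographic
    order of the sorted taxon labels.

    Raises if C(|v|, ki) exceeds ``cap`` — use the dynamic programs instead.
    """
    v = tree.root if clade is None else tree.find_clade(clade)
    size = tree.clade_size(v)
    if not 1 <= ki <= size:
        raise ValueError(f"ki must satisfy 1 <= ki <= |v| (got {ki}, |v|={size})")
    count = binomial_table(size, ki)(size, ki)
    if count > cap:
        raise ValueError(
            f"C({size},{ki}) = {count} subsets exceeds the enumeration cap "
            f"{cap}; use the dynamic programs for instances this large"
        )
    labels = sorted(tree.leaf_labels(v))
    values = tuple(
        pd_of_subset(tree, subset, v) for subset in combinations(labels, ki)
    )
    return PDDistribution(clade=v, ki=ki, values=values)


def oracle_stats(dist: PDDistribution) -> OracleStats:
    """Exact min, max, mean, and population variance of a PD multiset."""
    if not dist.values:
        raise ValueError("empty PD distribution")
    m = len(dist.values)
    mean = sum(dist.values, Fraction(0)) / m
    var = sum(((x - mean) ** 2 for x in dist.values), Fraction(0)) / m
    return OracleStats(min(dist.values), max(dist.values), mean, var)


def pd_by_edge_marking(tree: PhyloTree, subset, clade=None) -> Fraction:
    """PD via the edge-indicator formulation (independent of pd_of_subset).

    Sums w(e) over every edge e of the clade whose below-leaf set intersects
    the subset.
    """
    v = tree.root if clade is None else tree.find_clade(clade)
    want = frozenset(subset)
    if not want:
        raise ValueError("PD is undefined for an empty taxon set")
    missing = want - tree.leaf_labels(v)
    if missing:
        raise ValueError(f"taxa {sorted(missing)} are not leaves of the clade")
    total = Fraction(0)
    for u in tree.nodes_under(v, include_self=False):
        if tree.leaf_labels(u) & want:
            total += tree.length[u]
    return total
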