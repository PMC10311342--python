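"""Phylogenetic diversity of explicit taxon subsets.

Faith's PD of a subset S of leaves, evaluated within the clade rooted at v,
is the total branch length of the minimal subtree of T_v connecting S and v.
Equivalently it is the sum, over edges of T_v, of the edge weight times an
indicator that the edge lies on a path from v to some member of S.  Both
views are implemented here exactly (rational arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .tree import PhyloTree

__all__ = ["TaxonSubset", "pd_of_subset", "total_weight"]


@dataclass(frozen=True)
class TaxonSubset:
    """A set of taxon labels evaluated relative to a reference clade."""

    labels: frozenset[str]
    clade: int | None = field(default=None)  # node id; None means the root

    def __iter__(self):
        return iter(sorted(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


def _as_labels(subset) -> frozenset[str]:
    if isinstance(subset, TaxonSubset):
        return subset.labels
    return frozenset(subset)


def pd_of_subset(tree: PhyloTree, subset, clade=None) -> Fraction:
    """Exact PD of ``subset`` within the clade rooted at ``clade``.

    Parameters
    ----------
    subset : iterable of str or TaxonSubset
        Non-empty set of taxon labels; must all lie under ``clade``.
    clade : node reference, optional
        Defaults to the root (whole-tree PD).

    Returns
    -------
    Fraction
        Sum of branch lengths of the minimal subtree connecting the subset
        and the clade root.
    """
    labels = _as_labels(subset)
    if not labels:
        raise ValueError("PD is undefined for an empty taxon set")
    if clade is None and isinstance(subset, TaxonSubset):
        clade = subset.clade
    v = tree.root if clade is None else tree.find_clade(clade)
    leaf_map = tree.leaf_map
    in_clade = tree.nodes_under(v)
    edges: set[int] = set()
    for lab in sorted(labels):
        u = leaf_map.get(lab)
        if u is None or u not in in_clade:
            raise ValueError(f"taxon {lab!r} is not a leaf of the clade at node {v}")
        while u != v:
            if u in edges:
                break  # rest of the path already counted
            edges.add(u)
            u = tree.parent[u]
    return sum((tree.length[u] for u in edges), Fraction(0))


def total_weight(tree: PhyloTree, clade=None) -> Fraction:
    """Sum of all branch lengths within the clade rooted at ``clade``.

    For a leaf clade this is 0 (no edges).  At the root it is w(T), the PD of
    the full taxon set.
    """
    v = tree.root if clade is None else tree.find_clade(clade)
    return sum(
        (tree.length[u] for u in tree.nodes_under(v, include_self=False)),
        Fraction(0),
    )
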