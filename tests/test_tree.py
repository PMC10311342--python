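"""Tree structure, exact Newick round-trips, polytomy resolution, clades."""

import warnings
from fractions import Fraction
from itertools import combinations

import pytest

import cladepd as cp
from cladepd.tree import format_length

from conftest import (
    random_binary_tree,
    random_multifurcating_spec,
    spec_pd,
    spec_to_newick,
)


class TestParse:
    def test_example_structure(self, example):
        assert example.n_leaves == 5
        assert example.n_nodes == 9
        assert len(example.children[example.root]) == 2
        assert example.leaf_labels() == frozenset("ABCDE")
        assert example.leaf_labels(example.find_clade("ii")) == frozenset("CDE")

    def test_exact_decimal_literals(self):
        t = cp.parse_newick("(A:0.1,B:2.5e-2);")
        a, b = t.leaf_map["A"], t.leaf_map["B"]
        assert t.length[a] == Fraction(1, 10)
        assert t.length[b] == Fraction(1, 40)

    def test_cherry(self):
        t = cp.parse_newick("(A:1,B:2);")
        assert t.n_nodes == 3
        assert t.length[t.leaf_map["A"]] == 1
        assert t.length[t.leaf_map["B"]] == 2

    @pytest.mark.parametrize(
        "text, match",
        [
            ("((A:1,B:1),C:1);", "missing branch length"),
            ("(A:1,A:2);", "duplicate leaf label"),
            ("(A:1,B:-2);", "negative branch length"),
            ("(A:1,B:1,C:1);", "polytomy"),
            ("(A:1,(B:2):1);", "unifurcation"),
        ],
    )
    def test_invalid_inputs(self, text, match):
        with pytest.raises(ValueError, match=match):
            cp.parse_newick(text)

    def test_root_edge_length_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="root edge length"):
            t = cp.parse_newick("(A:1,B:2):5;")
        assert t.length[t.root] is None
        assert cp.total_weight(t) == 3

    def test_quoted_labels_and_comments(self):
        t = cp.parse_newick("('sp one':1,[note]'it''s':2);")
        assert t.leaf_labels() == frozenset({"sp one", "it's"})

    def test_single_leaf(self):
        t = cp.parse_newick("A;")
        assert t.n_nodes == 1
        assert cp.write_newick(t) == "A;"


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_trees(self, seed):
        t = random_binary_tree(seed, n=3 + seed)
        again = cp.parse_newick(cp.write_newick(t))
        assert again == t  # topology, labels, and exact lengths

    def test_example(self, example):
        assert cp.parse_newick(cp.write_newick(example)) == example

    @pytest.mark.parametrize(
        "frac, rendered",
        [
            (Fraction(1, 10), "0.1"),
            (Fraction(3), "3"),
            (Fraction(1, 8), "0.125"),
            (Fraction(1, 3), "1/3"),
            (Fraction(22, 7), "22/7"),
        ],
    )
    def test_length_rendering_lossless(self, frac, rendered):
        assert format_length(frac) == rendered
        assert Fraction(rendered) == frac


class TestResolvePolytomies:
    def test_triple(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = cp.parse_newick("(A:1,B:1,C:1);", resolve=True)
        assert t.is_binary
        assert t.n_nodes == 5
        assert cp.total_weight(t) == 3
        assert cp.pd_of_subset(t, "ABC") == 3

    def test_quad_has_seven_nodes(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = cp.parse_newick("(A:1,B:1,C:1,D:1);", resolve=True)
        assert t.is_binary and t.n_nodes == 7

    def test_binary_tree_unchanged(self, example):
        assert cp.resolve_polytomies(example) is example

    @pytest.mark.parametrize("seed", range(6))
    def test_pd_preserved_for_every_subset(self, seed):
        spec = random_multifurcating_spec(seed, n=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = cp.parse_newick(spec_to_newick(spec), resolve=True)
        assert t.is_binary
        labels = sorted(t.leaf_labels())
        for size in range(1, len(labels) + 1):
            for subset in combinations(labels, size):
                want = spec_pd(spec, frozenset(subset))
                assert cp.pd_of_subset(t, subset) == want


class TestCladeIndex:
    def test_example(self, example):
        idx = cp.clade_index(example)
        assert len(idx) == 9
        entries = list(idx)
        assert entries[-1].size == 5  # root last
        assert sum(1 for e in entries if e.size == 1) == 5

    def test_children_precede_parents(self):
        t = random_binary_tree(3, n=9)
        for v in t.postorder():
            for c in t.children[v]:
                assert c < v
            if not t.is_leaf(v):
                assert t.clade_size(v) == sum(t.clade_size(c) for c in t.children[v])
        assert sum(1 for v in t.postorder() if not t.is_leaf(v)) == t.n_leaves - 1

    def test_digest_stable_across_rotation(self, example):
        # same leaf set -> same digest regardless of child order
        rotated = cp.parse_newick("((E:4,(D:1,C:3)iii:2)ii:1,(B:4,A:3)i:1);")
        d1 = {e.label: e.leafset_digest for e in cp.clade_index(example) if e.label}
        d2 = {e.label: e.leafset_digest for e in cp.clade_index(rotated) if e.label}
        assert d1 == d2


def test_scaled_tree():
    t = cp.example_tree().scaled(Fraction(3, 7))
    assert cp.total_weight(t) == Fraction(19 * 3, 7)
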