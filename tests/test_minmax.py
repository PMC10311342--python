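"""Min/max PD dynamic program: oracle equality, backtracking, pair counts."""

import pytest

import cladepd as cp

from conftest import random_binary_tree


class TestExamples:
    def test_clade_ii(self, example):
        mm = cp.min_max_pd_tables(example, 2)
        assert mm.min_pd("ii", 2) == 6
        assert mm.max_pd("ii", 2) == 9

    def test_root(self, example):
        mm = cp.min_max_pd_tables(example, 5)
        assert mm.min_pd("root", 2) == 7  # {C, D}: 1 + 2 + 3 + 1
        assert mm.max_pd("root", 2) == 11  # {B, C}
        assert mm.min_pd("root", 5) == 19
        assert mm.max_pd("root", 5) == 19

    def test_leaf_clades_are_zero(self, example):
        mm = cp.min_max_pd_tables(example, 5)
        for leaf in "ABCDE":
            assert mm.min_pd(leaf, 1) == 0
            assert mm.max_pd(leaf, 1) == 0

    def test_k_out_of_range(self, example):
        with pytest.raises(ValueError):
            cp.min_max_pd_tables(example, 0)
        with pytest.raises(ValueError):
            cp.min_max_pd_tables(example, 6)

    def test_ki_beyond_clade_size_undefined(self, example):
        mm = cp.min_max_pd_tables(example, 5)
        with pytest.raises(ValueError, match="undefined"):
            mm.min_pd("ii", 4)


@pytest.mark.parametrize("seed", range(20))
def test_oracle_equivalence(seed):
    """DP tables equal brute-force min/max over all subsets, for every clade."""
    n = 3 + seed % 8
    t = random_binary_tree(seed + 500, n=n)
    mm = cp.min_max_pd_tables(t, n)
    for v in t.postorder():
        for ki in range(1, t.clade_size(v) + 1):
            stats = cp.oracle_stats(cp.enumerate_pd(t, v, ki))
            assert mm.min_pd(v, ki) == stats.min
            assert mm.max_pd(v, ki) == stats.max


@pytest.mark.parametrize("seed", range(5))
def test_monotone_in_ki_and_boundary(seed):
    t = random_binary_tree(seed, n=9)
    n = t.n_leaves
    mm = cp.min_max_pd_tables(t, n)
    for v in t.postorder():
        size = t.clade_size(v)
        prev_min = prev_max = None
        for ki in range(1, size + 1):
            lo, hi = mm.min_pd(v, ki), mm.max_pd(v, ki)
            assert lo <= hi
            if prev_min is not None:
                assert lo >= prev_min and hi >= prev_max
            prev_min, prev_max = lo, hi
        assert mm.min_pd(v, size) == mm.max_pd(v, size) == cp.total_weight(t, v)


@pytest.mark.parametrize("seed", range(5))
def test_sandwich_with_mean(seed):
    t = random_binary_tree(seed + 40, n=8)
    n = t.n_leaves
    mm = cp.min_max_pd_tables(t, n)
    mo = cp.moment_tables(t, n)
    for v in t.postorder():
        for ki in range(1, t.clade_size(v) + 1):
            assert mm.min_pd(v, ki) <= mo.avg_pd(v, ki) <= mm.max_pd(v, ki)


class TestBacktrack:
    def test_example_sets(self, example):
        mm = cp.min_max_pd_tables(example, 2)
        assert set(cp.backtrack_set(example, mm, "ii", 2, "min")) == {"C", "D"}
        assert set(cp.backtrack_set(example, mm, "ii", 2, "max")) == {"C", "E"}

    def test_full_clade_returns_all_leaves(self, example):
        mm = cp.min_max_pd_tables(example, 5)
        s = cp.backtrack_set(example, mm, "ii", 3, "min")
        assert set(s) == {"C", "D", "E"}

    @pytest.mark.parametrize("seed", range(8))
    def test_sets_reevaluate_to_table_value(self, seed):
        t = random_binary_tree(seed + 77, n=3 + seed)
        n = t.n_leaves
        mm = cp.min_max_pd_tables(t, n)
        for v in t.postorder():
            for ki in range(1, t.clade_size(v) + 1):
                for objective in ("min", "max"):
                    s = cp.backtrack_set(t, mm, v, ki, objective)
                    assert len(s) == ki
                    want = mm.min_pd(v, ki) if objective == "min" else mm.max_pd(v, ki)
                    assert cp.pd_of_subset(t, s, v) == want

    def test_deterministic(self, example):
        mm = cp.min_max_pd_tables(example, 5)
        a = cp.backtrack_set(example, mm, "root", 3, "min")
        b = cp.backtrack_set(example, mm, "root", 3, "min")
        assert a.labels == b.labels

    def test_invalid_objective(self, example):
        mm = cp.min_max_pd_tables(example, 2)
        with pytest.raises(ValueError):
            cp.backtrack_set(example, mm, "ii", 2, "median")


class TestPairCount:
    def test_cherry(self):
        t = cp.parse_newick("(A:1,B:2);")
        assert cp.pair_count(t, 2) == 4  # (0,0),(0,1),(1,0),(1,1)

    def test_example_matches_direct_enumeration(self, example):
        for k in (1, 2, 5):
            expected = 0
            for v in example.postorder():
                if example.is_leaf(v):
                    continue
                x, y = example.children[v]
                nx, ny = example.clade_size(x), example.clade_size(y)
                m = min(k, nx + ny)
                expected += sum(
                    1
                    for r in range(nx + 1)
                    for l in range(ny + 1)
                    if r + l <= m
                )
            assert cp.pair_count(example, k) == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_lower_bound_per_node(self, seed):
        t = random_binary_tree(seed, n=10)
        k = 4
        # I_v >= min(k, |v|) + 1 at every internal node, hence summed bound
        internal = [v for v in t.postorder() if not t.is_leaf(v)]
        lower = sum(min(k, t.clade_size(v)) + 1 for v in internal)
        assert cp.pair_count(t, k) >= lower
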