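import random
from fractions import Fraction

import pytest

import cladepd as cp

_DENOMS = [1, 2, 3, 4, 5, 8, 10]


def _rand_length(rng: random.Random) -> Fraction:
    return Fraction(rng.randint(1, 40), rng.choice(_DENOMS))


def random_binary_tree(seed: int, n: int) -> cp.PhyloTree:
    """Random binary topology with random positive rational branch lengths,
    built as a Newick string and parsed (exercising the exact parser)."""
    rng = random.Random(seed)
    frags = [f"L{i:02d}" for i in range(1, n + 1)]
    while len(frags) > 1:
        a = frags.pop(rng.randrange(len(frags)))
        b = frags.pop(rng.randrange(len(frags)))
        frags.append(f"({a}:{_rand_length(rng)},{b}:{_rand_length(rng)})")
    return cp.parse_newick(frags[0] + ";")


def random_multifurcating_spec(seed: int, n: int):
    """Random rooted tree spec (children, label, length) with node degrees
    2..4 and integer branch lengths; used to test polytomy resolution."""
    rng = random.Random(seed)
    frags = [([], f"L{i:02d}", Fraction(rng.randint(1, 9))) for i in range(1, n + 1)]
    while len(frags) > 1:
        deg = min(len(frags), rng.choice([2, 2, 3, 4]))
        children = [frags.pop(rng.randrange(len(frags))) for _ in range(deg)]
        frags.append((children, None, Fraction(rng.randint(1, 9))))
    children, label, _ = frags[0]
    return (children, label, None)


def spec_to_newick(spec) -> str:
    def render(node) -> str:
        children, label, length = node
        if children:
            s = "(" + ",".join(render(c) for c in children) + ")"
        else:
            s = label
        if length is not None:
            s += f":{length}"
        return s

    return render(spec) + ";"


def spec_pd(spec, taxa: frozenset) -> Fraction:
    """Independent PD on a nested tree spec: sum of lengths of edges whose
    subtree contains a selected taxon."""

    def walk(node):
        children, label, length = node
        total = Fraction(0)
        hit = False
        if children:
            for c in children:
                sub_total, sub_hit = walk(c)
                if sub_hit:
                    total += sub_total + (c[2] or 0)
                    hit = True
        else:
            hit = label in taxa
        return total, hit

    total, hit = walk(spec)
    if not hit:
        raise ValueError("no selected taxa in tree")
    return total


@pytest.fixture
def example():
    return cp.example_tree()
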