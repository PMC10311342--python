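"""Rooted phylogenies with exact rational branch lengths.

The central object is :class:`PhyloTree`, a rooted tree stored in post-order
arrays.  Branch lengths are :class:`fractions.Fraction` throughout: the Newick
reader converts each decimal literal to the exact rational it denotes
(``"0.1"`` becomes ``1/10``), so every statistic computed downstream is exact
rather than floating-point.  The dynamic programs in :mod:`cladepd.minmax` and
:mod:`cladepd.moments` require a full binary tree; multifurcating inputs can be
resolved deterministically with :func:`resolve_polytomies`.
"""

from __future__ import annotations

import hashlib
import sys
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

__all__ = [
    "PhyloTree",
    "CladeIndex",
    "CladeInfo",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "clade_index",
    "example_tree",
    "EXAMPLE_NEWICK",
]


class NewickError(ValueError):
    """Raised for syntactically invalid Newick input."""


class TreeValidationError(ValueError):
    """Raised when a tree violates the model's structural contract."""


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_DELIMS = "(),;:[]"


def _tokenize(text: str):
    """Yield Newick tokens: structural characters and ('text', s) items.

    Quoted labels ('...' with '' escaping a quote) and bracketed comments are
    handled per the standard dialect.
    """
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise NewickError("unterminated [comment] in Newick input")
            i = j + 1
        elif c in "(),;:":
            yield c
            i += 1
        elif c == "'":
            j = i + 1
            buf: list[str] = []
            while True:
                if j >= n:
                    raise NewickError("unterminated quoted label")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                    else:
                        j += 1
                        break
                else:
                    buf.append(text[j])
                    j += 1
            yield ("text", "".join(buf))
            i = j
        else:
            j = i
            while j < n and text[j] not in _DELIMS and not text[j].isspace():
                j += 1
            yield ("text", text[i:j])
            i = j


@contextmanager
def _recursion_headroom(depth: int):
    old = sys.getrecursionlimit()
    need = depth + 200
    if need > old:
        sys.setrecursionlimit(need)
    try:
        yield
    finally:
        sys.setrecursionlimit(old)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted tree over uniquely labeled leaves, in post-order arrays.

    Nodes are integers ``0 .. n_nodes-1`` in post-order (children before
    parents, root last), so the subtree of node ``v`` is the contiguous id
    range ``nodes_under(v)``.

    Parameters
    ----------
    children : sequence of tuples
        ``children[v]`` is ``()`` for a leaf, else the ordered child ids.
    length : sequence of Fraction or None
        ``length[v]`` is the weight ``w(v↓)`` of the edge above ``v``
        (``None`` for the root only).
    label : sequence of str or None
        Taxon name for leaves (required, unique); optional for internal nodes.
    """

    __slots__ = ("children", "parent", "length", "label",
                 "_sizes", "_node_counts", "_leaf_map")

    def __init__(
        self,
        children: Sequence[tuple[int, ...]],
        length: Sequence[Fraction | None],
        label: Sequence[str | None],
    ):
        self.children = [tuple(c) for c in children]
        self.length = list(length)
        self.label = list(label)
        n = len(self.children)
        parent: list[int | None] = [None] * n
        for v, ch in enumerate(self.children):
            for c in ch:
                if c >= v:
                    raise TreeValidationError("node ids must be post-ordered")
                if parent[c] is not None:
                    raise TreeValidationError(f"node {c} has two parents")
                parent[c] = v
        self.parent = parent
        self._sizes: list[int] | None = None
        self._node_counts: list[int] | None = None
        self._leaf_map: dict[str, int] | None = None
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.children)
        if n == 0:
            raise TreeValidationError("empty tree")
        roots = [v for v in range(n) if self.parent[v] is None]
        if roots != [n - 1]:
            raise TreeValidationError(
                "tree must have exactly one root, numbered last in post-order"
            )
        seen: set[str] = set()
        for v in range(n):
            ch = self.children[v]
            if len(ch) == 1:
                raise TreeValidationError(
                    f"node {self._describe(v)} has a single child (unifurcation)"
                )
            if not ch:
                lab = self.label[v]
                if not lab:
                    raise TreeValidationError(f"leaf {v} has no label")
                if lab in seen:
                    raise TreeValidationError(f"duplicate leaf label {lab!r}")
                seen.add(lab)
            w = self.length[v]
            if v == n - 1:
                if w is not None:
                    raise TreeValidationError("root must not carry an edge length")
                continue
            if w is None:
                raise TreeValidationError(
                    f"missing branch length on node {self._describe(v)}"
                )
            if w < 0:
                raise TreeValidationError(
                    f"negative branch length {w} on node {self._describe(v)}"
                )
            if w == 0:
                warnings.warn(
                    f"zero-length branch above node {self._describe(v)}",
                    stacklevel=3,
                )

    def _describe(self, v: int) -> str:
        lab = self.label[v]
        return f"{v} ({lab!r})" if lab else str(v)

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return len(self.children) - 1

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def n_leaves(self) -> int:
        return self.clade_size(self.root)

    @property
    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def require_binary(self) -> None:
        for v, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise TreeValidationError(
                    f"node {self._describe(v)} has {len(ch)} children; "
                    "resolve polytomies first (resolve_polytomies)"
                )

    def _compute_sizes(self) -> None:
        sizes = [0] * self.n_nodes
        counts = [0] * self.n_nodes
        for v in range(self.n_nodes):
            if self.is_leaf(v):
                sizes[v] = 1
                counts[v] = 1
            else:
                sizes[v] = sum(sizes[c] for c in self.children[v])
                counts[v] = 1 + sum(counts[c] for c in self.children[v])
        self._sizes = sizes
        self._node_counts = counts

    def clade_size(self, v: int) -> int:
        """Number of leaves |v| in the subtree rooted at v."""
        if self._sizes is None:
            self._compute_sizes()
        return self._sizes[v]  # type: ignore[index]

    def nodes_under(self, v: int, include_self: bool = True) -> range:
        """Post-order id range of the subtree rooted at v (contiguous)."""
        if self._node_counts is None:
            self._compute_sizes()
        cnt = self._node_counts[v]  # type: ignore[index]
        return range(v - cnt + 1, v + 1 if include_self else v)

    def postorder(self) -> range:
        return range(self.n_nodes)

    def leaves_under(self, v: int) -> Iterator[int]:
        for u in self.nodes_under(v):
            if self.is_leaf(u):
                yield u

    def leaf_labels(self, v: int | None = None) -> frozenset[str]:
        if v is None:
            v = self.root
        return frozenset(self.label[u] for u in self.leaves_under(v))

    @property
    def leaf_map(self) -> dict[str, int]:
        """Mapping taxon label -> leaf node id."""
        if self._leaf_map is None:
            self._leaf_map = {
                self.label[v]: v for v in range(self.n_nodes) if self.is_leaf(v)
            }
        return self._leaf_map

    # -- clade lookup ------------------------------------------------------

    def find_clade(self, key) -> int:
        """Resolve a clade reference to a node id.

        ``key`` may be a node id, the string ``"root"``, a node label, or an
        iterable of leaf labels (matched against exact clade leaf sets).
        """
        if isinstance(key, int):
            if not 0 <= key < self.n_nodes:
                raise KeyError(f"no node with id {key}")
            return key
        if isinstance(key, str):
            if key == "root":
                return self.root
            for v in range(self.n_nodes):
                if self.label[v] == key:
                    return v
            raise KeyError(f"no node labeled {key!r}")
        want = frozenset(key)
        for v in range(self.n_nodes):
            if self.clade_size(v) == len(want) and self.leaf_labels(v) == want:
                return v
        raise KeyError(f"no clade with leaf set {sorted(want)}")

    # -- transforms --------------------------------------------------------

    def scaled(self, c: Fraction) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``c``."""
        c = Fraction(c)
        if c < 0:
            raise ValueError("scale factor must be non-negative")
        lengths = [None if w is None else w * c for w in self.length]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PhyloTree(self.children, lengths, self.label)

    def __eq__(self, other) -> bool:  # structural equality
        return (
            isinstance(other, PhyloTree)
            and self.children == other.children
            and self.length == other.length
            and self.label == other.label
        )

    def __repr__(self) -> str:
        return f"<PhyloTree n_leaves={self.n_leaves} n_nodes={self.n_nodes}>"


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------


def _parse_length(literal: str, where: str) -> Fraction:
    try:
        return Fraction(literal)
    except (ValueError, ZeroDivisionError) as exc:
        raise NewickError(f"invalid branch length {literal!r} {where}") from exc


def parse_newick(text: str, resolve: bool = False) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Branch-length literals are converted to exact rationals (decimal and
    scientific notation, plus ``p/q`` as an extension for non-terminating
    rationals produced by :func:`write_newick`).  A length on the root edge is
    ignored with a warning.  Multifurcations raise unless ``resolve=True``, in
    which case they are resolved left-to-right with zero-length edges.
    """
    toks = list(_tokenize(text))
    if not toks:
        raise NewickError("empty Newick input")
    pos = 0

    def peek():
        return toks[pos] if pos < len(toks) else None

    def take():
        nonlocal pos
        t = peek()
        pos += 1
        return t

    def parse_node():
        # returns (children_list, label, length_or_None)
        tok = peek()
        children = []
        label = None
        if tok == "(":
            take()
            children.append(parse_node())
            while peek() == ",":
                take()
                children.append(parse_node())
            if take() != ")":
                raise NewickError("expected ')'")
            t = peek()
            if isinstance(t, tuple):
                label = take()[1]
        elif isinstance(tok, tuple):
            label = take()[1]
        else:
            raise NewickError(f"unexpected token {tok!r}")
        length = None
        if peek() == ":":
            take()
            t = take()
            if not isinstance(t, tuple):
                raise NewickError("expected a branch length after ':'")
            length = _parse_length(t[1], f"after node {label or '(internal)'}")
        return (children, label, length)

    depth = sum(1 for t in toks if t == "(")
    with _recursion_headroom(4 * depth):
        spec = parse_node()
    if take() != ";":
        raise NewickError("expected ';' at end of Newick input")
    if peek() is not None:
        raise NewickError("trailing content after ';'")

    if spec[2] is not None:
        warnings.warn(
            "root edge length in Newick input ignored (no edge exists above "
            "the root in the model)",
            stacklevel=2,
        )
        spec = (spec[0], spec[1], None)
    if resolve:
        spec = _resolve_spec(spec)
    else:
        _check_binary_spec(spec)
    return _build(spec)


def _check_binary_spec(spec) -> None:
    stack = [spec]
    while stack:
        children, label, _ = stack.pop()
        if len(children) > 2:
            raise TreeValidationError(
                f"polytomy ({len(children)} children) at node "
                f"{label or '(unnamed)'}; re-parse with resolve=True "
                "to resolve it"
            )
        stack.extend(children)


def _resolve_spec(spec):
    """Resolve polytomies left-to-right by inserting zero-length edges."""
    children, label, length = spec
    children = [_resolve_spec(c) for c in children]
    while len(children) > 2:
        first, second = children[0], children[1]
        joined = ([first, second], None, Fraction(0))
        children = [joined] + children[2:]
    return (children, label, length)


def _build(spec) -> PhyloTree:
    children_arr: list[tuple[int, ...]] = []
    length_arr: list[Fraction | None] = []
    label_arr: list[str | None] = []

    # iterative post-order numbering
    out: list[int] = []
    stack = [(spec, False)]
    ids: dict[int, int] = {}
    while stack:
        node, done = stack.pop()
        if done:
            ch_ids = tuple(ids[id(c)] for c in node[0])
            ids[id(node)] = len(children_arr)
            children_arr.append(ch_ids)
            label_arr.append(node[1])
            length_arr.append(node[2])
        else:
            stack.append((node, True))
            for c in reversed(node[0]):
                stack.append((c, False))
    return PhyloTree(children_arr, length_arr, label_arr)


def format_length(w: Fraction) -> str:
    """Render an exact rational branch length losslessly.

    Terminating rationals are written as plain decimals; others fall back to
    ``p/q``, which :func:`parse_newick` accepts.
    """
    num, den = w.numerator, w.denominator
    if den == 1:
        return str(num)
    # terminating iff den = 2^a * 5^b
    a = b = 0
    d = den
    while d % 2 == 0:
        d //= 2
        a += 1
    while d % 5 == 0:
        d //= 5
        b += 1
    if d != 1:
        return f"{num}/{den}"
    e = max(a, b)
    scaled = num * 10**e // den
    s = str(scaled).rjust(e + 1, "0")
    return f"{s[:-e]}.{s[-e:]}"


def _quote_if_needed(label: str) -> str:
    if any(c in _DELIMS or c.isspace() or c == "'" for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick; round-trips exactly through parse_newick."""
    parts: dict[int, str] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = _quote_if_needed(tree.label[v])
        else:
            inner = ",".join(parts.pop(c) for c in tree.children[v])
            s = f"({inner})" + (_quote_if_needed(tree.label[v]) if tree.label[v] else "")
        if tree.length[v] is not None:
            s += ":" + format_length(tree.length[v])
        parts[v] = s
    return parts[tree.root] + ";"


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Return a full binary tree over the same leaves.

    Each polytomy is resolved deterministically left-to-right by inserting
    zero-length edges, so the total edge weight and the PD of every taxon
    subset are unchanged.
    """
    if tree.is_binary:
        return tree

    def to_spec(v: int):
        return ([to_spec(c) for c in tree.children[v]], tree.label[v], tree.length[v])

    with _recursion_headroom(4 * tree.n_nodes):
        spec = _resolve_spec(to_spec(tree.root))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _build(spec)


# ---------------------------------------------------------------------------
# Clade index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeInfo:
    clade_id: int          # post-order rank
    size: int              # leaf count |v|
    label: str             # node label, or "" if absent
    leafset_digest: str    # stable digest of the sorted leaf-label set


@dataclass(frozen=True)
class CladeIndex:
    entries: tuple[CladeInfo, ...]

    def __iter__(self) -> Iterator[CladeInfo]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _digest(labels: Iterable[str]) -> str:
    joined = "|".join(sorted(labels))
    return hashlib.sha1(joined.encode()).hexdigest()[:12]


def clade_index(tree: PhyloTree) -> CladeIndex:
    """Enumerate all clades in post-order with stable identifiers."""
    entries = []
    for v in tree.postorder():
        entries.append(
            CladeInfo(
                clade_id=v,
                size=tree.clade_size(v),
                label=tree.label[v] or "",
                leafset_digest=_digest(tree.leaf_labels(v)),
            )
        )
    return CladeIndex(tuple(entries))


# ---------------------------------------------------------------------------
# Built-in example tree
# ---------------------------------------------------------------------------

#: Five-taxon worked example used throughout the docs and tests.  Within the
#: clade labeled "ii" (leaves C, D, E), the three 2-taxon subsets have PD
#: 6 ({C,D}), 9 ({C,E}) and 7 ({D,E}), giving mean 22/3 and population
#: variance 14/9.
EXAMPLE_NEWICK = "((A:3,B:4)i:1,((C:3,D:1)iii:2,E:4)ii:1);"


def example_tree() -> PhyloTree:
    """The five-taxon example tree ``((A:3,B:4)i:1,((C:3,D:1)iii:2,E:4)ii:1);``.

    Total edge weight 19; PD of {A, B, D} from the root is 12.
    """
    return parse_newick(EXAMPLE_NEWICK)
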