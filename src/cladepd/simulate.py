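"""Birth-death tree simulation and the Monte-Carlo sampling baseline.

`simulate_birth_death` wraps dendropy's constant-rate birth-death process
conditioned on a target number of extant tips (extinct lineages pruned), then
converts the result to a :class:`~cladepd.tree.PhyloTree` with branch lengths
quantized to exact rationals at 1e-9 resolution (clamped to a strictly
positive minimum).  A seed fully determines the output.

`sample_pd_estimate` is the estimator the exact algorithms are benchmarked
against: draw uniform size-k taxon subsets in batches, track the running mean
and population variance of their PD, and stop either when both are within a
relative tolerance of supplied exact values (``vs_truth``) or when successive
batch-end estimates stabilize (``self_stabilizing``).  Sampling runs in
floating point — it is the approximate baseline, not the exact method.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from dendropy.model import birthdeath

from .tree import PhyloTree, _build

__all__ = [
    "BirthDeathParams",
    "SamplingEstimate",
    "simulate_birth_death",
    "sample_pd_estimate",
    "draw_uniform_subsets",
]

_QUANTUM = 10**9  # branch-length quantization denominator


@dataclass(frozen=True)
class BirthDeathParams:
    """Constant-rate birth-death process conditioned on n extant taxa."""

    n: int
    birth: float = 1.0
    death: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")
        if not 0 <= self.death < self.birth:
            raise ValueError("death rate must satisfy 0 <= death < birth")
        if self.n < 2:
            raise ValueError("need at least 2 extant taxa")


def _quantize(length: float) -> Fraction:
    q = Fraction(round(length * _QUANTUM), _QUANTUM)
    return q if q > 0 else Fraction(1, _QUANTUM)


def simulate_birth_death(params: BirthDeathParams) -> PhyloTree:
    """Simulate a rooted binary tree with exactly ``params.n`` extant leaves.

    Leaves are labeled t1..tn in left-to-right order.  Identical parameters
    and seed yield an identical tree.
    """
    params.validate()
    rng = random.Random(params.seed)
    dtree = birthdeath.birth_death_tree(
        params.birth,
        params.death,
        num_extant_tips=params.n,
        rng=rng,
    )
    counter = [0]

    def convert(node, is_root: bool):
        children = [convert(c, False) for c in node.child_nodes()]
        label = None
        if not children:
            counter[0] += 1
            label = f"t{counter[0]}"
        length = None if is_root else _quantize(node.edge.length or 0.0)
        return (children, label, length)

    tree = _build(convert(dtree.seed_node, True))
    assert tree.n_leaves == params.n
    return tree


@dataclass
class SamplingEstimate:
    """State of a Monte-Carlo mean/variance PD estimate."""

    ki: int
    batch: int
    tol: float
    mode: str
    seed: int
    n_samples: int = 0
    mean_pd: float = 0.0
    var_pd: float = 0.0  # population variance of the sampled PDs
    converged: bool = False


def draw_uniform_subsets(
    n_leaves: int, ki: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """(count, ki) array of leaf indices; each row a uniform size-ki subset."""
    u = rng.random((count, n_leaves))
    return np.argpartition(u, ki - 1, axis=1)[:, :ki]


def _leaf_paths(tree: PhyloTree) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pad each leaf's root-path edge ids into a matrix for fast PD batches."""
    labels = [tree.label[v] for v in tree.leaves_under(tree.root)]
    paths = []
    for lab in labels:
        u = tree.leaf_map[lab]
        path = []
        while u != tree.root:
            path.append(u)
            u = tree.parent[u]
        paths.append(path)
    depth = max(len(p) for p in paths)
    pad = tree.n_nodes  # dummy edge id with weight 0
    mat = np.full((len(paths), depth), pad, dtype=np.int64)
    for i, p in enumerate(paths):
        mat[i, : len(p)] = p
    weights = np.zeros(tree.n_nodes + 1)
    for v in range(tree.n_nodes - 1):
        weights[v] = float(tree.length[v])
    return mat, weights, labels


def _within(est: float, target: float, tol: float) -> bool:
    if target == 0:
        return abs(est) <= tol
    return abs(est - target) <= tol * abs(target)


def sample_pd_estimate(
    tree: PhyloTree,
    ki: int,
    batch: int = 200,
    tol: float = 1e-3,
    mode: str = "vs_truth",
    truth: tuple | None = None,
    seed: int = 0,
    max_samples: int = 10**7,
) -> SamplingEstimate:
    """Estimate mean and variance PD by uniform subset sampling.

    Parameters
    ----------
    ki : int
        Subset size, 1 <= ki <= n.
    batch : int
        Samples drawn between convergence checks (default 200).
    tol : float
        Relative convergence tolerance (default 0.1%).
    mode : str
        ``"vs_truth"``: stop when both running estimates are within ``tol``
        of the exact values supplied in ``truth=(mean, variance)``.
        ``"self_stabilizing"``: stop when successive batch-end estimates both
        move by less than ``tol`` relatively.
    max_samples : int
        Hard cap; on reaching it the estimate is returned with
        ``converged=False``.
    """
    n = tree.n_leaves
    if not 1 <= ki <= n:
        raise ValueError(f"ki must satisfy 1 <= ki <= n (got {ki}, n={n})")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if mode not in ("vs_truth", "self_stabilizing"):
        raise ValueError("mode must be 'vs_truth' or 'self_stabilizing'")
    if mode == "vs_truth":
        if truth is None:
            raise ValueError("vs_truth mode requires truth=(mean, variance)")
        true_mean, true_var = float(truth[0]), float(truth[1])

    mat, weights, _ = _leaf_paths(tree)
    n_cols = weights.shape[0]
    rng = np.random.default_rng(seed)
    est = SamplingEstimate(ki=ki, batch=batch, tol=tol, mode=mode, seed=seed)
    s1 = 0.0
    s2 = 0.0
    m = 0
    prev: tuple[float, float] | None = None
    rows = np.repeat(np.arange(batch), ki * mat.shape[1])
    while m < max_samples:
        picks = draw_uniform_subsets(n, ki, batch, rng)
        edge_ids = mat[picks].reshape(batch, -1)
        mask = np.zeros((batch, n_cols), dtype=bool)
        mask[rows, edge_ids.ravel()] = True
        pd_vals = mask @ weights
        s1 += float(pd_vals.sum())
        s2 += float((pd_vals * pd_vals).sum())
        m += batch
        mean = s1 / m
        var = max(0.0, s2 / m - mean * mean)
        est.n_samples, est.mean_pd, est.var_pd = m, mean, var
        if mode == "vs_truth":
            if _within(mean, true_mean, tol) and _within(var, true_var, tol):
                est.converged = True
                return est
        else:
            if prev is not None and _within(mean, prev[0], tol) and _within(
                var, prev[1], tol
            ):
                est.converged = True
                return est
            prev = (mean, var)
    return est
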