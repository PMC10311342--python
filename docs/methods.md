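# Methods

## Model and definitions

A phylogeny here is a rooted full binary tree *T* over a taxon set *X* of
size *n*, with a weight w(e) ≥ 0 on every edge.  For a non-empty S ⊆ X, the
phylogenetic diversity PD_T(S) is the total weight of the minimal subtree
connecting S and the root ρ; equivalently, the sum over edges of w(e) times
an indicator that the clade below e contains a member of S.  For a node v,
T_v is the clade rooted at v, |v| its leaf count, and v^k the collection of
size-k subsets of T_v's leaves.  The statistics computed per clade and per
size 1 ≤ kᵢ ≤ min(k, |v|) are

- δ(v, kᵢ) = min PD over v^kᵢ, Δ(v, kᵢ) = max PD over v^kᵢ,
- α(v, kᵢ) = mean PD of a uniform draw from v^kᵢ,
- ψ(v, kᵢ) = population variance of PD over v^kᵢ
  (denominator C(|v|, kᵢ), never kᵢ−1: ψ is the variance of the uniform
  distribution over subsets, not a sample estimate).

Sizes kᵢ > |v| are undefined and the accessors refuse them.

## Recurrences

All four tables are filled in one post-order pass each.  At an internal node
v with children x, y, a size-i subset splits into r taxa under x and
l = i − r under y.  With the k=0 sentinel value 0, the min/max tables use the
single unified loop

    opt(v, i) = opt over r in [max(0, i−|y|), min(|x|, i)] of
                opt(x, r) + w(x↓)·[r ≥ 1] + opt(y, l) + w(y↓)·[l ≥ 1]

which covers the three cases (all taxa under x, all under y, split) at once.
Optimal subsets are recovered by backtracking, re-deriving the argmin at
each node; ties break toward the smallest r (fewest taxa from the left
child), so reported sets are deterministic.

The moment tables propagate the unnormalized sums β = Σ PD and γ = Σ PD²
(see the `cladepd.moments` module docstring for the full recurrences).  The
split terms are weighted by binomial counts of the complementary child's
subsets, taken from an exact Pascal-triangle table with the convention
C(i, j) = 0 for j > i or j < 0 — under which the all-under-one-child terms
vanish automatically whenever the subset size exceeds that child's leaf
count.  α and ψ are formed as exact rationals at readout.  The γ recurrence
restricts the split sum to 1 ≤ r, l ≤ i − 1; the one-child cases enter only
through their closed-form terms, since adding them to the loop as r = 0 or
l = 0 endpoints would count them twice.

## Exact arithmetic

Branch lengths are parsed from their decimal literals into rationals, so
"0.1" contributes exactly 1/10.  Internally every DP scales all lengths by
the LCM of their denominators and runs on plain Python big integers — the
integer results are divided by the scale (squared, for γ) only at the
accessor, which is exact and avoids per-operation gcd normalization.  With
integer inputs, β and γ are integers; the tests use this as an exactness
witness.  A float mode (`exact=False` on the moment tables) runs the same
recurrences in IEEE doubles for very large n·k; it is approximate, clearly
flagged, and never used by the test suite.

Rendering happens only at output: 6 significant digits by default
(half-even), `--precision` to change it, `--exact-rationals` for verbatim
p/q.  The mean 22/3 of the worked example prints as 7.33333; two-decimal
displays elsewhere truncate toward zero (22/3 → 7.33, 14/9 → 1.55).

## Trees and I/O

Newick input follows the standard dialect (quoted labels, bracket comments
skipped).  Contracts: every non-root edge must carry a length; a root-edge
length is ignored with a warning (no edge exists above ρ in the model);
duplicate leaf labels, negative lengths, and unifurcations are errors;
zero lengths are allowed with a warning.  Multifurcations are rejected by
default — min/max sets are resolution-invariant but clade enumeration is
not, so silent resolution could mislead — and resolved on request,
deterministically left-to-right with zero-length edges, which provably
preserves the PD of every subset.  The writer emits terminating rationals
as plain decimals and falls back to `p/q` (accepted back by the parser) for
non-terminating ones, so round-trips are lossless.  Clades are identified by
post-order rank, plus the node label when present and a 12-hex digest of the
sorted leaf-label set, making outputs stable across runs and child orders.

## Simulator and sampling baseline

Test trees come from the constant-rate birth–death process (defaults:
speciation 1.0, extinction 0.5 per lineage per unit time — the classic
regime where extinction prunes half the speciations) conditioned on a target
number of extant tips, via dendropy with a seeded RNG; extinct lineages are
pruned, leaves are relabeled t1..tn left-to-right, and branch lengths are
quantized to exact rationals at 1e-9 resolution (clamped strictly positive).
The simulator emulates realistic tree shapes and depth profiles; it does not
emulate rate heterogeneity across lineages, sampling fractions, or
measurement error in branch lengths, so passing tests demonstrate
correctness of the combinatorics on plausible topologies, not robustness to
real-data artifacts (the exact algorithms are topology-agnostic, so this
limitation concerns the diagnostics, not the results).

The Monte-Carlo baseline draws uniform size-k subsets in batches of 200 and
tracks the running mean and population variance of their PD in floating
point.  Two stopping rules: `vs_truth` (stop when both estimates are within
a relative 0.1% of supplied exact values — only usable for benchmarking
against the DP) and `self_stabilizing` (stop when successive batch-end
estimates move less than the tolerance — the default in the CLI, where truth
is unknown).  A hard cap of 10^7 samples returns `converged=False` rather
than looping forever.  Batch size 200 and tolerance 0.1% are the
benchmarking convention the exact algorithms are compared against; the
population (not sample) variance is used for consistency with ψ.

## Problem sizes in the tests

The test suite checks exact equality of all four DP tables against
brute-force enumeration on 200 random birth–death topologies with 3–12
leaves and random positive rational weights (every clade, every size) —
beyond 12 leaves enumeration, not the DP, is the bottleneck.  Sampling
convergence is verified on a 500-leaf tree at k = 50, and the O(kn)
pair-count diagnostic I(T)/(kn) ≤ 4 on trees of 64–1024 leaves with k = n;
the constant 4 is an empirical working bound (the theory gives only
O(kn)), and observed ratios sit near 1.

## Known limitations

- Unrooted trees, trees without branch lengths, and NEXUS/PhyloXML input
  are out of scope.
- ψ is population variance only; no sample-variance option.
- The float fast mode has no error bound; use it only where approximate
  screening of very large n·k is acceptable.
- Wall-clock comparisons are hardware-dependent and are reported
  informationally (README example), never asserted.
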