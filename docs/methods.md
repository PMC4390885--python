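# Methods

## Problem and assumptions

`mircensus` reconstructs the evolutionary history of gene-family sizes —
paralog counts — on a fixed, rooted species tree. It was designed around
animal miRNA families, whose unusual properties anchor three modelling
assumptions:

1. **Single origin (Dollo).** A family arises exactly once and can only be
   lost afterwards. miRNA precursors are short but under strong stabilizing
   selection; an independent second origin of the same recognizable sequence
   is considered negligible once repeat-derived, very-high-copy families are
   removed (the curation stage's copy cap exists for exactly this reason).
2. **Known phylogeny.** The species tree is input, rooted, and taken as
   correct. Contested nodes should be encoded as multifurcations rather than
   arbitrarily resolved — multifurcations are first-class throughout.
3. **No within-edge event ordering.** Duplications and losses of the same
   family on the same edge are not resolved into an order; the cost of an
   edge depends only on the parent and child counts. This is the resolution
   limit of count data without positional (synteny) information.

Branch lengths are accepted on input and ignored: the reconstruction is
cladogram-based, since the per-edge change cost makes no reference to time.

## Origin dating

A family's origin is the branch entering the LCA of all leaves where it is
observed (count ≥ 1; no minimum-copy threshold). Presence data with few
false positives make this a conservative estimate — losses can pull the LCA
of the *survivors* below the true origin, but never above it. Families
observed in a single species originate on that terminal branch. When the
LCA is the global root there is no parent branch; such families are flagged
`at_root` ("at or before the root").

The LCA is computed in linear time per family: with the tree's fixed
preorder, take the first leaf `p` and last leaf `q` of the present set; the
LCA of the whole set equals the LCA of `p` and `q` (preorder makes the
present set's span contiguous in the Euler sense), found by walking `q`'s
root path against `p`'s. Correctness is tested exhaustively against a
path-intersection oracle for every subset of trees up to 12 leaves.

## The dynamic program

Notation and recursions are given in the README. Implementation choices:

- **State space.** Counts range over `0..P_m` where `P_m` is the maximum
  observed count in the family subtree; widening the range cannot improve
  the optimum (any assignment above the leaf maximum can be lowered without
  increasing cost under a monotone per-copy cost). A property test
  enumerates beyond the cap to confirm.
- **Dollo enforcement.** Nodes with `P_v ≥ 1` have `S_{0v} = ∞`; nodes with
  `P_v = 0` are pinned to count 0 (score vector `[0, ∞, …]`). The second
  half means a family that dies out is charged exactly once, on the edge
  entering the maximal all-absent subtree — never inside it, and never
  outside `T_m`. Loss edges are therefore exactly the edges from `P ≥ 1`
  parents to `P = 0` children within `T_m`, a characterization asserted in
  tests independently of the DP.
- **Infinity.** Infeasible states carry IEEE `inf` in float score vectors.
  `inf + finite = inf` propagates correctly through the child sums, ordering
  against any finite score is exact, and no saturation arithmetic is needed.
  Scores of feasible solutions are exact: they are sums of products of small
  integers and the cost weights (integers by default), far below any float
  precision limit.
- **Cost model.** `delta(k→j)` = `dup_weight·max(j−k,0) +
  loss_weight·max(k−j,0)`, scaled by an optional per-child-node factor;
  defaults (1, 1, none) give the plain counting score `|k−j|`. Weights are
  nonnegative reals; `delta(k,k) = 0` always.
- **Tie-breaking.** Among co-optimal counts the smallest is chosen, top-down
  from the family root and independently per child. This is deterministic
  and conservative (fewest inferred ancestral paralogs). Since co-optimal
  assignments are common (the very first worked example has two), the exact
  number of co-optimal full assignments is counted by a parallel product/sum
  recursion over argmin sets and reported as `n_co_optimal`.
- **Complexity.** `O(|T_m| · P_m²)` per family: one `(P_m+1)²` cost-matrix
  minimization per edge, vectorized with numpy.

## Per-branch census

Aggregation over families is pure bookkeeping with two deliberate choices:

- The denominator of **relative gain** is the number of families present at
  the node itself (gains included); **relative loss** divides by families
  present at the parent. Zero denominators yield `NaN`/`NA`, never 0 — "no
  families that could be lost" must not masquerade as "no losses observed".
- Copy-level **flux** (copies gained / lost per edge) counts only edges
  inside each family's `T_m`. Under the default cost, a family's total flux
  equals its parsimony score — an identity the tests assert per family.

## Curation of homology hits

The filter consumes standard 12-column tabular BLAST output plus precursor
and mature FASTA. A hit is accepted iff E ≤ `max_evalue` (default 1e-10),
the aligned query span covers ≥ `min_query_coverage` (default 0.90,
measured as `(qend−qstart+1)/query_length`, 1-based inclusive), and the
span contains every annotated mature interval of the query (a precursor
with both arms annotated must have both spanned). Coverage is measured on
the query side because it is computable from tabular output alone. Both
thresholds are inclusive at the boundary. Family admission drops families
recovered nowhere and families with **more than** `max_copies_per_species`
copies (default 100) in any one species — strictly greater, so a species at
exactly the cap is kept. Mature-to-precursor assignment defaults to
substring containment (a mature may map to several paralogous precursors);
an explicit assignment rule can be supplied, and a mature matching nothing
is flagged for manual mapping rather than silently dropped. No structural
(secondary-structure alignment) criterion is applied: accepted hits carry no
vetting beyond the three rules above.

## Simulator

The generator draws the model's own forward process: one copy at the origin
node (drawn uniformly over all nodes, or fixed), then on each edge below it
every parental copy duplicates independently with probability `p_dup`, and
every resulting copy is lost independently with probability `p_loss` —
duplications before losses, a fixed order that keeps the event log exactly
replayable. Probabilities are per edge, not per unit branch length,
mirroring the cladogram-based reconstruction. Defaults are
`p_dup = p_loss = 0.05` per copy per edge: sparse turnover that yields
mostly single-copy families with occasional small expansions, the regime
typical of conserved miRNA families. Histories extinct at every leaf are
redrawn (all-zero profiles are inadmissible) and the redraw count is
reported; conditioning on non-extinction slightly inflates mean counts,
which the branching-process test accounts for. Under dup-then-loss the
expected per-leaf copy number below a root origin at depth `d` is
`((1+p_dup)(1−p_loss))^d`.

What the simulator does *not* emulate: sequence evolution and homology-search
sensitivity (false negatives from assembly gaps or divergence), correlated
loss after genome duplications, and gene conversion between paralogs.
Passing recovery tests therefore demonstrates correctness of the
reconstruction algorithm under its own model assumptions, not robustness of
the biological pipeline to missing data.

## Verification design

The primary correctness surface is exhaustive: for every rooted
multifurcating topology *shape* (up to isomorphism — labelings are
redundant when all count vectors are enumerated) up to six leaves, and
every leaf-count vector with entries ≤ 3, the DP's score, returned
assignment, and co-optimum count are compared against brute-force
enumeration of all Dollo-feasible assignments (1, 1, 2, 5, 12, 33 shapes
for 1–6 leaves; ~185k reconstructions). The 90 seven-leaf shapes are
covered with seeded random count vectors. The pytest suite runs a lighter
split of the same check (exhaustive through five leaves). LCA verification
is exhaustive over all leaf subsets for 2–12-leaf trees plus 10⁴ random
subsets of a 200-leaf tree. Simulation-based checks use 1000 families each
(30-leaf trees for the event-free limit, 16-leaf for pure-loss
conservativeness); census identities use batches of 150–200 families on
12-leaf trees. All randomness flows from explicit integer seeds.

## Known limitations

- Parsimony lower-bounds the true number of events; rate estimates from the
  census are floors, not unbiased estimates. Equal-rate regimes (e.g., a
  duplication and loss on the same edge) are invisible by assumption 3.
- The origin is systematically too recent when early losses prune all
  basal lineages — inherent to LCA dating, not repairable from count data.
- Parsimony loss edges place extinctions at the *top* of a maximal absent
  subtree; if lineages died independently deeper down, the census
  attributes one loss where the truth had several (and conversely never
  splits one).
- Interior reconstructions are frequently non-unique; downstream analyses
  sensitive to exact ancestral counts should check `n_co_optimal`.
- The count matrix is taken at face value: paralogs collapsed in an
  assembly, or inflated by unplaced scaffolds, propagate directly into the
  reconstruction.
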