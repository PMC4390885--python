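# mircensus

Gain/loss census of gene families — built for microRNA families — on a
rooted species phylogeny. Given per-species paralog counts for many
families, `mircensus` dates each family's origin, reconstructs the number of
paralogs at every ancestral node, identifies the branches on which families
were lost, and aggregates per-branch statistics of innovation and loss
across the whole family set. A homology-hit curation stage turns raw BLAST
tabular output into trustworthy copy counts, and a simulator generates
synthetic family histories with known ground truth for validation.

## The model

miRNA precursors are so strongly conserved that a convincing sequence
homolog essentially never arises twice independently (repeat-derived
families, where this fails, are excluded by a copy-number cap). This
justifies **Dollo parsimony**: each family arises exactly once and may only
be lost thereafter. The origin of family *m* is therefore dated to the
branch leading to the **last common ancestor** (LCA) of all species where
the family is observed; the subtree rooted there is written *T_m*. Because
false positives are rare under stringent curation, this LCA is a
*conservative* (possibly too recent) estimate of the true origin.

Ancestral paralog counts are reconstructed with a **Sankoff-style dynamic
program** over *T_m*. Writing *u ⊳ v* for "u is a child of v":

- *P_v* = max_{u ⊳ v} *P_u*, the largest observed count below *v*
  (at a leaf, the observed count). No optimum assigns an ancestor more
  copies than *P_m*, so the state space is *k* ∈ {0, …, *P_m*}.
- *S_kv* = minimal cost of the subtree below *v* given *v* carries *k*
  copies. Leaves are pinned to their data (*S_kℓ* = 0 iff *k* is the
  observed count, else ∞); interior nodes satisfy

  *S_kv* = Σ_{u ⊳ v} min_j ( *S_ju* + δ_u(j, k) ),

  with each child minimized independently. The **Dollo constraint** enters
  through the *k* = 0 row: *S_0v* = ∞ whenever *P_v* ≥ 1 (a node cannot be
  empty while its subtree holds an observed copy), and a node with
  *P_v* = 0 is pinned to zero copies.
- δ_u(j, k), the cost of going from *k* copies at the parent to *j* at
  child *u*, defaults to |k − j| — the number of copies duplicated or
  deleted. Asymmetric duplication/loss weights and per-node multipliers are
  available through `CostModel`.

The optimal score is *S* = min_k *S_km*; backtracing (smallest count on
ties, applied top-down) yields the per-node counts. **Loss edges** are the
edges whose parent has *k* > 0 and child *k* = 0 — equivalently, the
branches leading to maximal subtrees of *T_m* with no observed member.

The per-branch census then reports, for every node *v*: families present,
families gained (origin = *v*), families lost on the edge into *v*,
**relative gain** = gains / families present at *v*, and **relative loss**
= losses / families present at the parent of *v*, plus copy-level flux
(copies gained/lost per edge summed over families).

## Worked example

A five-species vertebrate cladogram and three families:

```sh
cat tree.nwk
# (((human,mouse)mammal,chicken)amniote,(zebrafish,medaka)teleost)vertebrate;

cat counts.tsv
# family_id  human  mouse  chicken  zebrafish  medaka
# mir-17     4      4      2        6          5
# mir-novel  2      1      0        0          0
# mir-lost   1      1      0        1          1

mircensus parsimony --tree tree.nwk --counts counts.tsv --out pars
cat pars/families.tsv
# family_id   origin_node  total_score  n_co_optimal  n_present_species
# mir-17      vertebrate   4.0          2             5
# mir-novel   mammal       1.0          2             2
# mir-lost    vertebrate   1.0          1             4
```

`mir-novel` is observed only in the two mammals, so its origin is dated to
the mammal ancestor; one duplication (human 2 vs mouse 1, score 1) happened
since. `mir-lost` is observed everywhere except chicken: it originates at
the vertebrate root and its single event is a loss on the chicken branch —
visible in the per-family table as the `is_loss_edge` flag on `chicken`.
`mir-17` needs four copy-number changes; two co-optimal ancestral
assignments exist and the reported one uses the smallest counts.

```sh
mircensus summarize --tree tree.nwk --parsimony-dir pars --out cen
cat cen/census.tsv
# node        families_present  gains  losses  relative_gain  relative_loss  copies_gained  copies_lost
# vertebrate  2                 2      0       1.0            NA             0              0
# amniote     2                 0      0       0.0            0.0            0              0
# mammal      3                 1      0       0.333…         0.0            0              0
# human       3                 0      0       0.0            0.0            1              0
# chicken     1                 0      1       0.0            0.5            0              3
# …
```

Gains sum to 3 (one per family — Dollo), chicken's relative loss is 0.5
(one of the two families present at the amniote ancestor), and the root's
relative loss is `NA` (no parent branch exists). The same numbers are
written onto the tree as comment annotations:

```
…chicken[&count=1,gains=0,losses=1])amniote[&count=2,gains=0,losses=0],…
```

The census can also be produced in one step
(`mircensus summarize --counts counts.tsv …`); the two routes are
byte-identical. `mircensus simulate` generates count matrices with a known
event history, and `mircensus filter` curates BLAST tabular hits
(E ≤ 1e-10, ≥90% query coverage, mature-sequence containment, per-species
copy cap) into the count-matrix format consumed above.

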