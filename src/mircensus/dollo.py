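"""Dollo-constrained Sankoff parsimony over paralog counts.

The reconstruction problem: given a rooted species tree and the observed
number of paralogs of one gene family in each extant species, assign a copy
number to every ancestral node so that the summed per-edge change cost is
minimal, under the Dollo rule that the family arises exactly once and can
only be lost thereafter.

Notation (used throughout this module):

* ``m``      — the family's origin node, the LCA of all species where the
  family is observed.  All computation is confined to the subtree ``T_m``
  rooted at ``m``; nodes outside it carry count 0 and are charged nothing.
* ``P_v``    — the maximum observed count in the subtree below ``v``
  (``P_v = max over children u of P_u``; at a leaf, the observed count).
  No optimal solution assigns more copies to an ancestor than the maximum
  seen at any leaf, so the dynamic program ranges over ``k = 0..P_m``.
* ``S_kv``   — minimal cost of the subtree below ``v`` given that ``v``
  carries exactly ``k`` copies.  Leaves are pinned to their data
  (``S_kl = 0`` iff ``k`` equals the observed count, else infinity).
  Interior nodes satisfy
  ``S_kv = sum over children u of min_j (S_ju + delta_u(j, k))``;
  each child is minimized independently because min distributes over the
  sum.  The Dollo constraint enters through the ``k = 0`` row: a node with
  ``P_v >= 1`` may never carry 0 copies (``S_0v = infinity``), while a node
  whose whole subtree is empty (``P_v = 0``) is pinned to 0 — the family
  dies on the edge entering the maximal all-absent subtree, never inside it.

The per-edge cost ``delta_u(j, k)`` defaults to ``|k - j|``, the number of
copies duplicated or deleted on the edge; asymmetric duplication/loss
weights and per-node multipliers are supported via :class:`CostModel`.

Infinity is represented by IEEE ``inf``, which propagates correctly through
addition and can never be mistaken for a feasible score.

Backtracing picks, among co-optimal counts, the smallest — top-down from the
family root, children resolved independently — which is deterministic and
conservative (fewest inferred ancestral paralogs).  The number of co-optimal
full assignments is also counted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CountProfile
from .origins import find_lca_preorder
from .treeio import PhyloTree

__all__ = [
    "CostModel",
    "ParsimonyTable",
    "Reconstruction",
    "subtree_maxima",
    "sankoff_fill",
    "backtrace",
    "reconstruct_family",
    "reconstruction_table",
]


@dataclass(frozen=True)
class CostModel:
    """Per-edge cost of changing the paralog count from parent to child.

    ``delta(k, j, u) = dup_weight * max(j - k, 0) + loss_weight * max(k - j, 0)``,
    optionally scaled by a per-node factor for the child ``u``.  The default
    (both weights 1, no factors) is the simple counting score ``|k - j|``.
    ``delta(k, k, u) = 0`` always.
    """

    dup_weight: float = 1.0
    loss_weight: float = 1.0
    node_factor: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dup_weight < 0 or self.loss_weight < 0:
            raise ValueError("cost weights must be nonnegative")
        if any(f < 0 for f in self.node_factor.values()):
            raise ValueError("node factors must be nonnegative")

    def delta(self, parent_k: int, child_j: int, child: str) -> float:
        change = child_j - parent_k
        base = self.dup_weight * change if change > 0 else self.loss_weight * -change
        return base * self.node_factor.get(child, 1.0)

    def edge_cost_matrix(self, child: str, k_max: int) -> np.ndarray:
        """Matrix ``C[k, j] = delta(k, j, child)`` for ``k, j in 0..k_max``."""
        k = np.arange(k_max + 1)
        diff = k[None, :] - k[:, None]  # j - k
        cost = np.where(diff > 0, self.dup_weight * diff, -self.loss_weight * diff)
        return cost.astype(float) * self.node_factor.get(child, 1.0)


@dataclass
class ParsimonyTable:
    """Filled dynamic-programming table for one family.

    ``scores[v]`` is the vector ``S_kv`` for ``k = 0..P_m`` over every node
    ``v`` of the family subtree ``T_m``; entries outside ``T_m`` are absent.
    """

    family_id: str
    family_root: str
    tree: PhyloTree
    profile: CountProfile
    subtree_max: dict[str, int]
    scores: dict[str, np.ndarray]

    @property
    def k_max(self) -> int:
        return self.subtree_max[self.family_root]


@dataclass(frozen=True)
class Reconstruction:
    """Most-parsimonious history of one family.

    ``counts`` covers every node of the family subtree ``T_m`` (leaves
    included, pinned to their data); nodes outside ``T_m`` implicitly carry
    0 copies and are charged no events.  ``loss_edges`` are the edges on
    which the family goes extinct: parent count > 0, child count = 0.
    ``n_co_optimal`` counts the full assignments attaining ``total_score``.
    """

    family_id: str
    origin_node: str
    counts: Mapping[str, int]
    total_score: float
    loss_edges: frozenset[tuple[str, str]]
    n_co_optimal: int

    def count_of(self, node: str) -> int:
        return self.counts.get(node, 0)


def subtree_maxima(tree: PhyloTree, profile: CountProfile) -> dict[str, int]:
    """``P_v`` for every node: the largest observed count below ``v``."""
    maxima: dict[str, int] = {}
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            maxima[node] = profile.count(tree.label[node])
        else:
            maxima[node] = max(maxima[u] for u in kids)
    return maxima


def sankoff_fill(
    tree: PhyloTree,
    profile: CountProfile,
    cost: CostModel | None = None,
    origin: str | None = None,
) -> ParsimonyTable:
    """Fill ``S_kv`` bottom-up over the family subtree.

    ``origin`` defaults to the LCA of the present leaves; passing a node
    that is not an ancestor of every present leaf is an error.
    """
    cost = cost or CostModel()
    present = profile.present
    if origin is None:
        origin = find_lca_preorder(tree, present)
    else:
        if origin not in tree:
            raise ValueError(f"origin node {origin!r} not on the tree")
        for lab in present:
            if not tree.is_ancestor_or_self(origin, tree.leaf_by_label(lab)):
                raise ValueError(
                    f"origin {origin!r} is not an ancestor of present leaf {lab!r}"
                )

    maxima = subtree_maxima(tree, profile)
    k_max = maxima[origin]
    scores: dict[str, np.ndarray] = {}
    for node in tree.postorder(origin):
        s = np.full(k_max + 1, math.inf)
        if maxima[node] == 0:
            # Whole subtree empty: Dollo pins the node to 0 copies; the loss
            # is charged on the edge entering this subtree, not below it.
            s[0] = 0.0
            scores[node] = s
            continue
        kids = tree.children[node]
        if not kids:
            s[profile.count(tree.label[node])] = 0.0
        else:
            s[1:] = 0.0
            for u in kids:
                cmat = cost.edge_cost_matrix(u, k_max)
                # best contribution of child u for every parent count k
                s[1:] += np.min(scores[u][None, :] + cmat[1:, :], axis=1)
            # k = 0 stays infinite: P_v >= 1 forbids an empty ancestor
        scores[node] = s
    return ParsimonyTable(
        family_id=profile.family_id,
        family_root=origin,
        tree=tree,
        profile=profile,
        subtree_max=maxima,
        scores=scores,
    )


def _count_optima(table: ParsimonyTable, cost: CostModel) -> int:
    """Exact number of co-optimal full assignments (exact integer count)."""
    tree = table.tree
    k_max = table.k_max
    ways: dict[str, list[int]] = {}
    for node in tree.postorder(table.family_root):
        s = table.scores[node]
        kids = tree.children[node]
        if not kids or table.subtree_max[node] == 0:
            ways[node] = [1 if math.isfinite(s[k]) else 0 for k in range(k_max + 1)]
            continue
        w = []
        for k in range(k_max + 1):
            if not math.isfinite(s[k]):
                w.append(0)
                continue
            total = 1
            for u in kids:
                cand = table.scores[u] + cost.edge_cost_matrix(u, k_max)[k]
                best = cand.min()
                total *= sum(
                    ways[u][j] for j in range(k_max + 1) if cand[j] == best
                )
            w.append(total)
        ways[node] = w
    root_s = table.scores[table.family_root]
    best = root_s.min()
    return sum(
        ways[table.family_root][k]
        for k in range(k_max + 1)
        if root_s[k] == best
    )


def backtrace(table: ParsimonyTable, cost: CostModel | None = None) -> Reconstruction:
    """Extract a most-parsimonious assignment from a filled table.

    Ties are broken toward the smallest optimal count, applied top-down at
    the family root and then independently per child.
    """
    cost = cost or CostModel()
    tree = table.tree
    k_max = table.k_max
    root_s = table.scores[table.family_root]
    total = float(root_s.min())
    assign: dict[str, int] = {
        table.family_root: int(np.flatnonzero(root_s == root_s.min())[0])
    }
    for node in table.tree.subtree_nodes(table.family_root):  # preorder
        k = assign[node]
        for u in tree.children[node]:
            cand = table.scores[u] + cost.edge_cost_matrix(u, k_max)[k]
            assign[u] = int(np.flatnonzero(cand == cand.min())[0])

    losses = frozenset(
        (node, u)
        for node in assign
        for u in tree.children[node]
        if assign[node] > 0 and assign[u] == 0
    )
    return Reconstruction(
        family_id=table.family_id,
        origin_node=table.family_root,
        counts=assign,
        total_score=total,
        loss_edges=losses,
        n_co_optimal=_count_optima(table, cost),
    )


def reconstruct_family(
    tree: PhyloTree,
    profile: CountProfile,
    cost: CostModel | None = None,
) -> Reconstruction:
    """Origin dating + DP fill + backtrace for one family.

    Runtime is ``O(|T_m| * P_m^2)``: one ``(P_m+1) x (P_m+1)`` minimization
    per edge of the family subtree.
    """
    cost = cost or CostModel()
    profile.validate_against(tree)
    table = sankoff_fill(tree, profile, cost)
    return backtrace(table, cost)


def reconstruction_table(tree: PhyloTree, rec: Reconstruction) -> pd.DataFrame:
    """Per-node report of one reconstruction, in tree preorder.

    Covers all tree nodes; nodes outside the family subtree carry count 0
    and ``in_family_subtree = False``.
    """
    in_tm = set(rec.counts)
    loss_children = {u for (_v, u) in rec.loss_edges}
    rows = {
        "family_id": rec.family_id,
        "node": list(tree.preorder),
        "count": [rec.count_of(v) for v in tree.preorder],
        "in_family_subtree": [v in in_tm for v in tree.preorder],
        "is_loss_edge": [v in loss_children for v in tree.preorder],
        "origin_node": rec.origin_node,
        "total_score": rec.total_score,
        "n_co_optimal": rec.n_co_optimal,
    }
    return pd.DataFrame(rows)
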