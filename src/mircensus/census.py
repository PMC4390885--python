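"""Per-branch gain/loss census across a set of family reconstructions.

For each tree node ``v`` the census tallies, over all families analyzed:

* ``families_present`` — families with at least one copy assigned at ``v``;
* ``gains``            — families whose origin node is ``v`` (each family is
  gained exactly once, so gains sum to the number of families);
* ``losses``           — families lost on the edge entering ``v``;
* ``relative_gain``    — gains divided by the families present at ``v``
  itself (gains included in the denominator);
* ``relative_loss``    — losses divided by the families present at the
  parent of ``v``; undefined at the root.

Zero denominators yield a missing value (NaN), not zero: "no families that
could be lost" is not the same observation as "no losses".

:func:`paralog_flux` resolves the same histories at copy resolution: per
edge, the number of copies gained by duplication and lost by deletion, plus
the (ancestor count, descendant count) pairs from which expansion patterns
across e.g. whole-genome duplications can be tabulated.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .dollo import Reconstruction
from .treeio import PhyloTree

__all__ = [
    "aggregate",
    "paralog_flux",
    "ancestor_descendant_pairs",
    "census_table",
    "census_annotations",
]


def _check_same_tree(tree: PhyloTree, reconstructions: Sequence[Reconstruction]) -> None:
    nodes = set(tree.preorder)
    for rec in reconstructions:
        if rec.origin_node not in nodes or not set(rec.counts) <= nodes:
            raise ValueError(
                f"reconstruction of family {rec.family_id!r} refers to nodes "
                "that are not on this tree (mixed trees?)"
            )


def aggregate(
    tree: PhyloTree, reconstructions: Sequence[Reconstruction]
) -> pd.DataFrame:
    """Per-node gain/loss census, indexed by node in tree preorder."""
    _check_same_tree(tree, reconstructions)
    nodes = list(tree.preorder)
    present = {v: 0 for v in nodes}
    gains = {v: 0 for v in nodes}
    losses = {v: 0 for v in nodes}
    for rec in reconstructions:
        gains[rec.origin_node] += 1
        for v, k in rec.counts.items():
            if k >= 1:
                present[v] += 1
        for _parent, child in rec.loss_edges:
            losses[child] += 1

    rel_gain = {
        v: gains[v] / present[v] if present[v] > 0 else math.nan for v in nodes
    }
    rel_loss = {}
    for v in nodes:
        p = tree.parent[v]
        if p is None or present[p] == 0:
            rel_loss[v] = math.nan
        else:
            rel_loss[v] = losses[v] / present[p]

    out = pd.DataFrame(
        {
            "node": nodes,
            "families_present": [present[v] for v in nodes],
            "gains": [gains[v] for v in nodes],
            "losses": [losses[v] for v in nodes],
            "relative_gain": [rel_gain[v] for v in nodes],
            "relative_loss": [rel_loss[v] for v in nodes],
        }
    ).set_index("node")
    return out


def paralog_flux(
    tree: PhyloTree, reconstructions: Sequence[Reconstruction]
) -> pd.DataFrame:
    """Per-edge copy-number turnover, indexed by the edge's child node.

    ``copies_gained`` sums ``max(child - parent, 0)`` over families and
    ``copies_lost`` sums ``max(parent - child, 0)``; only edges inside each
    family's subtree contribute (the family does not exist elsewhere).
    Under the default unit cost, a family's summed flux over all edges
    equals its parsimony score.
    """
    _check_same_tree(tree, reconstructions)
    nodes = list(tree.preorder)
    gained = {v: 0 for v in nodes}
    lost = {v: 0 for v in nodes}
    for rec in reconstructions:
        for v in rec.counts:
            for u in tree.children[v]:
                if u not in rec.counts:
                    continue
                change = rec.counts[u] - rec.counts[v]
                if change > 0:
                    gained[u] += change
                else:
                    lost[u] -= change
    return pd.DataFrame(
        {
            "node": nodes,
            "copies_gained": [gained[v] for v in nodes],
            "copies_lost": [lost[v] for v in nodes],
        }
    ).set_index("node")


def ancestor_descendant_pairs(
    tree: PhyloTree,
    reconstructions: Sequence[Reconstruction],
    ancestor: str,
    descendant: str,
) -> pd.DataFrame:
    """Per-family (ancestor count, descendant count) pairs for two nodes.

    The raw material for expansion scatter plots, e.g. paralog counts before
    versus after a genome duplication.  Families absent at both nodes are
    omitted.  ``descendant`` must lie below ``ancestor``.
    """
    _check_same_tree(tree, reconstructions)
    if not tree.is_ancestor_or_self(ancestor, descendant):
        raise ValueError(f"{descendant!r} is not a descendant of {ancestor!r}")
    rows = []
    for rec in reconstructions:
        a, d = rec.count_of(ancestor), rec.count_of(descendant)
        if a > 0 or d > 0:
            rows.append((rec.family_id, a, d))
    return pd.DataFrame(
        rows, columns=["family_id", "ancestor_count", "descendant_count"]
    )


def census_table(
    tree: PhyloTree, reconstructions: Sequence[Reconstruction]
) -> pd.DataFrame:
    """Census and copy flux merged into one per-node table (TSV-ready)."""
    return aggregate(tree, reconstructions).join(
        paralog_flux(tree, reconstructions)
    )


def census_annotations(census: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Gains/losses annotation map for ``treeio.write_annotated``."""
    out: dict[str, dict[str, float]] = {}
    for node, row in census.iterrows():
        out[str(node)] = {
            "count": int(row["families_present"]),
            "gains": int(row["gains"]),
            "losses": int(row["losses"]),
        }
    return out
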