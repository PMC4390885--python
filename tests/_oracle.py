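"""Independent brute-force oracles used to verify the fast implementations.

Everything in here is deliberately naive and shares no code path with the
package: LCA by path intersection, reconstruction by exhaustive enumeration
of Dollo-feasible assignments, topologies by recursive set partitioning.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence

from mircensus.counts import CountProfile
from mircensus.dollo import CostModel
from mircensus.treeio import PhyloTree


def brute_lca(tree: PhyloTree, labels: Sequence[str]) -> str:
    """Deepest node common to the root paths of every listed leaf."""
    paths = [set(tree.path_to_root(tree.leaf_by_label(l))) for l in labels]
    common = set.intersection(*paths)
    return max(common, key=tree.preorder_index.__getitem__)


def set_partitions(items: tuple) -> Iterator[list[tuple]]:
    """All partitions of ``items`` into nonempty blocks (order-insensitive)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [(first,) + part[i]] + part[i + 1 :]
        yield [(first,)] + part


def all_topologies(labels: tuple[str, ...]) -> Iterator[PhyloTree]:
    """Every rooted multifurcating topology on the given labeled leaves."""
    counter = itertools.count()

    def build(leaf_set: tuple[str, ...]) -> Iterator[tuple[str, dict]]:
        if len(leaf_set) == 1:
            yield leaf_set[0], {leaf_set[0]: ()}
            return
        for part in set_partitions(leaf_set):
            if len(part) < 2:
                continue
            for combo in itertools.product(*(build(tuple(b)) for b in part)):
                root = f"v{next(counter)}"
                children: dict[str, tuple[str, ...]] = {
                    root: tuple(r for r, _ in combo)
                }
                for _, sub in combo:
                    children.update(sub)
                yield root, children

    for root, children in build(labels):
        yield PhyloTree(root, children)


def shape_key(tree: PhyloTree, node: str | None = None):
    """Canonical form of the unlabeled shape (for isomorphism dedup)."""
    node = node or tree.root
    kids = tree.children[node]
    if not kids:
        return ()
    return tuple(sorted(shape_key(tree, k) for k in kids))


def topology_representatives(labels: tuple[str, ...]) -> list[PhyloTree]:
    """One labeled representative per topology shape (up to isomorphism)."""
    seen: set = set()
    out = []
    for tree in all_topologies(labels):
        key = shape_key(tree)
        if key not in seen:
            seen.add(key)
            out.append(tree)
    return out


def brute_reconstruct(
    tree: PhyloTree,
    profile: CountProfile,
    cost: CostModel | None = None,
) -> tuple[float, list[dict[str, int]]]:
    """Exhaustive minimum over all Dollo-feasible assignments on T_m.

    Feasibility: leaves pinned to data; a node whose subtree holds any
    observed copy must carry >= 1; a node whose subtree is empty carries 0.
    Returns the minimal total edge cost and every assignment attaining it.
    """
    cost = cost or CostModel()
    origin = brute_lca(tree, sorted(profile.present))
    nodes = tree.subtree_nodes(origin)
    maxima: dict[str, int] = {}
    for v in reversed(nodes):
        kids = tree.children[v]
        maxima[v] = (
            profile.count(tree.label[v])
            if not kids
            else max(maxima[u] for u in kids)
        )
    k_max = maxima[origin]

    domains: list[range] = []
    free: list[str] = []
    fixed: dict[str, int] = {}
    for v in nodes:
        if not tree.children[v]:
            fixed[v] = profile.count(tree.label[v])
        elif maxima[v] == 0:
            fixed[v] = 0
        else:
            free.append(v)
            domains.append(range(1, k_max + 1))
    edges = [(v, u) for v in nodes for u in tree.children[v]]

    best = float("inf")
    argmins: list[dict[str, int]] = []
    for combo in itertools.product(*domains):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        total = sum(cost.delta(assign[v], assign[u], u) for v, u in edges)
        if total < best:
            best, argmins = total, [assign]
        elif total == best:
            argmins.append(assign)
    return best, argmins
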