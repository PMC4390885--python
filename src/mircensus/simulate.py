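"""Synthetic family histories with known ground truth.

The generator replays the very model the reconstruction assumes: a family
arises once (one copy at its origin node) and evolves down the tree by
per-copy duplication and loss on each edge.  On the edge into a child, each
of the ``n`` parental copies duplicates independently with probability
``p_dup``; each of the resulting copies is then lost independently with
probability ``p_loss`` (duplications before losses, a fixed order that keeps
replay deterministic — within-edge event ordering is not modelled, matching
the reconstruction's assumptions).  Events are per edge, not per unit branch
length: the reconstruction is cladogram-based, so simulated time is too.

Default rates are 0.05 duplications and 0.05 losses per copy per edge —
sparse turnover producing mostly single-copy families with occasional small
expansions, the regime typical of conserved miRNA families.

Because an all-zero profile is inadmissible (an unobserved family does not
exist for the analysis), histories that drift to extinction everywhere are
redrawn; the number of redraws is recorded.

Everything is reproducible: one integer seed drives a family, and a batch
derives independent per-family seeds from its own seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .counts import CountProfile
from .treeio import PhyloTree

__all__ = ["SimulatedFamily", "evolve_family", "batch", "random_tree"]

DEFAULT_P_DUP = 0.05
DEFAULT_P_LOSS = 0.05

_MAX_REDRAWS = 10_000


@dataclass(frozen=True)
class SimulatedFamily:
    """One simulated history: origin, per-edge events, resulting leaf data.

    ``event_log`` holds ``(parent, child, signed copy change)`` triples with
    the duplication gain (positive) and loss (negative) on each edge below
    the origin; zero-change edges are omitted.  Replaying the log from one
    copy at ``true_origin`` yields exactly ``leaf_counts``.
    """

    family_id: str
    true_origin: str
    event_log: tuple[tuple[str, str, int], ...]
    leaf_counts: CountProfile
    seed: int
    n_redraws: int = 0

    @property
    def n_events(self) -> int:
        """Total simulated copy changes (sum of absolute event sizes)."""
        return sum(abs(delta) for _, _, delta in self.event_log)


def _draw_history(
    tree: PhyloTree,
    origin: str,
    p_dup: float,
    p_loss: float,
    rng: np.random.Generator,
) -> tuple[dict[str, int], list[tuple[str, str, int]]]:
    count: dict[str, int] = {origin: 1}
    log: list[tuple[str, str, int]] = []
    for v in tree.subtree_nodes(origin):  # preorder: parents first
        for u in tree.children[v]:
            n = count[v]
            dups = int(rng.binomial(n, p_dup)) if n else 0
            survivors = n + dups
            losses = int(rng.binomial(survivors, p_loss)) if survivors else 0
            count[u] = survivors - losses
            if dups:
                log.append((v, u, dups))
            if losses:
                log.append((v, u, -losses))
    return count, log


def evolve_family(
    tree: PhyloTree,
    origin: str = "random",
    p_dup: float = DEFAULT_P_DUP,
    p_loss: float = DEFAULT_P_LOSS,
    seed: int = 0,
    family_id: str = "sim",
) -> SimulatedFamily:
    """Simulate one family from a single ancestral copy at ``origin``.

    ``origin="random"`` draws the origin uniformly over all tree nodes
    (interior and leaves).  Histories extinct at every leaf are redrawn from
    the same random stream; the redraw count is reported.
    """
    if not (0 <= p_dup < 1 and 0 <= p_loss < 1):
        raise ValueError("event probabilities must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if origin == "random":
        origin = str(rng.choice(list(tree.preorder)))
    elif origin not in tree:
        raise ValueError(f"origin node {origin!r} not on the tree")

    redraws = 0
    while True:
        count, log = _draw_history(tree, origin, p_dup, p_loss, rng)
        leaf_counts = {
            tree.label[v]: count.get(v, 0) for v in tree.leaves()
        }
        if any(c >= 1 for c in leaf_counts.values()):
            break
        redraws += 1
        if redraws > _MAX_REDRAWS:
            raise RuntimeError(
                "family went extinct in every draw; loss rate too extreme"
            )
    return SimulatedFamily(
        family_id=family_id,
        true_origin=origin,
        event_log=tuple(log),
        leaf_counts=CountProfile(family_id, leaf_counts),
        seed=seed,
        n_redraws=redraws,
    )


def batch(
    tree: PhyloTree,
    n_families: int,
    p_dup: float | tuple[float, float] = DEFAULT_P_DUP,
    p_loss: float | tuple[float, float] = DEFAULT_P_LOSS,
    seed: int = 0,
    origin: str = "random",
) -> list[SimulatedFamily]:
    """Simulate ``n_families`` independent families, reproducibly.

    Rate arguments may be scalars or ``(low, high)`` ranges sampled
    uniformly per family.  Family seeds are derived from ``seed`` so the
    whole batch is a pure function of its arguments.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_families)
    families = []
    for i in range(n_families):
        pd_i = (
            float(rng.uniform(*p_dup)) if isinstance(p_dup, tuple) else p_dup
        )
        pl_i = (
            float(rng.uniform(*p_loss)) if isinstance(p_loss, tuple) else p_loss
        )
        families.append(
            evolve_family(
                tree,
                origin=origin,
                p_dup=pd_i,
                p_loss=pl_i,
                seed=int(seeds[i]),
                family_id=f"fam{i:05d}",
            )
        )
    return families


def write_event_logs(families: Sequence[SimulatedFamily], path: str | Path) -> None:
    """JSON sidecar with the ground-truth history of every family."""
    payload = {
        fam.family_id: {
            "true_origin": fam.true_origin,
            "seed": fam.seed,
            "n_redraws": fam.n_redraws,
            "events": [
                {"parent": p, "child": c, "copies": d}
                for p, c, d in fam.event_log
            ],
        }
        for fam in families
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def random_tree(
    n_leaves: int,
    seed: int | np.random.Generator = 0,
    multifurcation_p: float = 0.0,
    labels: Sequence[str] | None = None,
) -> PhyloTree:
    """Random rooted tree by repeated joining of subtree groups.

    With probability ``multifurcation_p`` a join merges three groups instead
    of two, producing multifurcating test topologies.  Leaf labels default
    to ``t1..tN``.
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("labels length must equal n_leaves")

    children: dict[str, tuple[str, ...]] = {lab: () for lab in labels}
    groups = list(labels)
    next_id = 0
    while len(groups) > 1:
        k = 3 if (len(groups) >= 3 and rng.random() < multifurcation_p) else 2
        picks = sorted(rng.choice(len(groups), size=k, replace=False), reverse=True)
        merged = tuple(groups.pop(i) for i in picks)
        node = f"i{next_id}"
        next_id += 1
        children[node] = merged
        groups.append(node)
    return PhyloTree(groups[0], children, {lab: lab for lab in labels})
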