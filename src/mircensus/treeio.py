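"""Rooted phylogenies with multifurcations, preorder indexing and annotated newick I/O.

The container is deliberately minimal: an ordered, rooted tree over opaque
string node identifiers.  Branch lengths carry no meaning for a
cladogram-based parsimony analysis, so they are parsed and discarded.  A
fixed depth-first preorder of the ordered representation is computed once at
construction; it is what the linear-time LCA shortcut and the dynamic
program traverse.

Annotated output uses a small comment dialect: each node may carry a
``[&key=value,...]`` comment block directly after its label, with keys drawn
from :data:`ANNOTATION_KEYS` (``count``, ``gains``, ``losses``).  The dialect
is a subset of the widely used ampersand/BEAST comment style and round-trips
through :func:`parse_annotated`.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "parse_annotated",
    "write_annotated",
    "to_newick",
    "ANNOTATION_KEYS",
]

#: Fixed vocabulary for node annotations in the newick comment dialect.
ANNOTATION_KEYS = ("count", "gains", "losses")


class NewickParseError(ValueError):
    """Malformed newick input; the message names the offending position."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate labels, orphan nodes, ...)."""


class PhyloTree:
    """A rooted, ordered, possibly multifurcating tree.

    Parameters
    ----------
    root:
        Identifier of the root node.
    children:
        Map from node identifier to the ordered sequence of its children.
        Every node reachable from the root must appear as a key (leaves map
        to an empty sequence).
    label:
        Map from node identifier to taxon/clade name.  Labels are mandatory
        and unique for leaves; interior labels are optional.  Leaves missing
        from the map default to their own identifier.

    Attributes
    ----------
    preorder:
        Tuple of node identifiers in depth-first preorder of the ordered
        representation (root first, children in their stored order).
    preorder_index:
        Map node -> integer rank in ``preorder``.
    parent:
        Map node -> parent identifier (``None`` for the root).
    """

    __slots__ = (
        "root",
        "children",
        "parent",
        "label",
        "preorder",
        "preorder_index",
        "_leaf_by_label",
    )

    def __init__(
        self,
        root: str,
        children: Mapping[str, Sequence[str]],
        label: Mapping[str, str] | None = None,
    ) -> None:
        self.root = root
        self.children: dict[str, tuple[str, ...]] = {
            node: tuple(kids) for node, kids in children.items()
        }
        if root not in self.children:
            raise TreeValidationError(f"root {root!r} missing from children map")

        parent: dict[str, str | None] = {root: None}
        order: list[str] = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            kids = self.children.get(node)
            if kids is None:
                raise TreeValidationError(f"node {node!r} missing from children map")
            for kid in kids:
                if kid in parent:
                    raise TreeValidationError(
                        f"node {kid!r} has more than one parent (or a cycle)"
                    )
                parent[kid] = node
            stack.extend(reversed(kids))
        if len(order) != len(self.children):
            orphans = sorted(set(self.children) - set(order))
            raise TreeValidationError(f"nodes unreachable from root: {orphans}")

        self.parent = parent
        self.preorder: tuple[str, ...] = tuple(order)
        self.preorder_index: dict[str, int] = {v: i for i, v in enumerate(order)}

        lab = dict(label) if label else {}
        for leaf in self.leaves():
            lab.setdefault(leaf, leaf)
            if not lab[leaf]:
                raise TreeValidationError(f"leaf {leaf!r} has an empty label")
        self.label: dict[str, str] = lab

        by_label: dict[str, str] = {}
        for leaf in self.leaves():
            name = lab[leaf]
            if name in by_label:
                raise TreeValidationError(f"duplicate leaf label {name!r}")
            by_label[name] = leaf
        self._leaf_by_label = by_label

    # -- basic queries -----------------------------------------------------

    def is_leaf(self, node: str) -> bool:
        return not self.children[node]

    def leaves(self) -> tuple[str, ...]:
        """Leaf identifiers in preorder."""
        return tuple(v for v in self.preorder if not self.children[v])

    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(self.label[v] for v in self.leaves())

    def leaf_by_label(self, name: str) -> str:
        try:
            return self._leaf_by_label[name]
        except KeyError:
            raise KeyError(f"no leaf labelled {name!r} on the tree") from None

    def postorder(self, subtree_root: str | None = None) -> Iterator[str]:
        """Depth-first postorder, optionally restricted to a subtree."""
        start = self.root if subtree_root is None else subtree_root
        out: list[str] = []
        stack = [start]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return reversed(out)

    def subtree_nodes(self, subtree_root: str) -> tuple[str, ...]:
        """All nodes of the subtree rooted at ``subtree_root``, preorder."""
        out: list[str] = []
        stack = [subtree_root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children[node]))
        return tuple(out)

    def path_to_root(self, node: str) -> tuple[str, ...]:
        """Nodes from ``node`` up to and including the root."""
        path = [node]
        while (up := self.parent[path[-1]]) is not None:
            path.append(up)
        return tuple(path)

    def is_ancestor_or_self(self, anc: str, node: str) -> bool:
        cur: str | None = node
        while cur is not None:
            if cur == anc:
                return True
            cur = self.parent[cur]
        return False

    def __contains__(self, node: str) -> bool:
        return node in self.children

    def __len__(self) -> int:
        return len(self.preorder)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PhyloTree(root={self.root!r}, n_nodes={len(self)}, "
            f"n_leaves={len(self.leaves())})"
        )


# -- parsing ---------------------------------------------------------------


def _parse(text: str) -> tuple[PhyloTree, dict[str, dict[str, float]]]:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "duplicate" in msg.lower() or "multiple" in msg.lower():
            raise TreeValidationError(msg) from exc
        raise NewickParseError(msg) from exc

    # Assign stable identifiers in preorder: leaves take their taxon label,
    # labelled interior nodes their label, unnamed interior nodes a synthetic
    # identifier derived from the preorder rank (reproducible across runs).
    ids: dict[int, str] = {}
    seen: set[str] = set()
    for rank, nd in enumerate(dtree.preorder_node_iter()):
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("leaf without a label in newick input")
            ident = nd.taxon.label
            if ident in seen:
                raise TreeValidationError(f"duplicate leaf label {ident!r}")
        else:
            ident = nd.label if nd.label else f"node{rank}"
            while ident in seen:  # interior label clashing with another id
                ident += "_"
        seen.add(ident)
        ids[id(nd)] = ident

    children: dict[str, tuple[str, ...]] = {}
    label: dict[str, str] = {}
    annotations: dict[str, dict[str, float]] = {}
    for nd in dtree.preorder_node_iter():
        ident = ids[id(nd)]
        children[ident] = tuple(ids[id(c)] for c in nd.child_nodes())
        if nd.is_leaf():
            label[ident] = nd.taxon.label
        elif nd.label:
            label[ident] = nd.label
        note: dict[str, float] = {}
        for ann in nd.annotations:
            if ann.name in ANNOTATION_KEYS:
                value = float(ann.value)
                note[ann.name] = int(value) if value.is_integer() else value
        if note:
            annotations[ident] = note

    tree = PhyloTree(ids[id(dtree.seed_node)], children, label)
    return tree, annotations


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted newick string (branch lengths accepted and ignored).

    The tree is taken as rooted at the outermost newick node; no rerooting
    is attempted.  Unnamed interior nodes receive deterministic synthetic
    identifiers (``node<preorder rank>``).
    """
    return _parse(text)[0]


def parse_annotated(text: str) -> tuple[PhyloTree, dict[str, dict[str, float]]]:
    """Parse newick carrying ``[&count=..,gains=..,losses=..]`` comments.

    Returns the tree and a map node -> {key: value} for the nodes that
    carried annotations.  Inverse of :func:`write_annotated`.
    """
    return _parse(text)


# -- serialization ----------------------------------------------------------

_NEEDS_QUOTE = set("()[]{}/\\,;:=*'\"`<>+- \t\n")


def _fmt_label(name: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _fmt_value(value: float) -> str:
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, int) or (isinstance(value, float) and value.is_integer()):
        return str(int(value))
    return repr(float(value))


def write_annotated(
    tree: PhyloTree,
    annotations: Mapping[str, Mapping[str, float]] | None = None,
) -> str:
    """Serialize a tree to newick with per-node comment annotations.

    ``annotations`` maps node identifiers to key/value pairs; keys must come
    from :data:`ANNOTATION_KEYS`.  An empty or missing map yields plain
    newick.  Interior nodes whose identifier is synthetic (not present in
    ``tree.label``) are written without a name, so topology serialization is
    the exact inverse of parsing.
    """
    notes = {k: dict(v) for k, v in (annotations or {}).items()}
    for node, pairs in notes.items():
        if node not in tree:
            raise TreeValidationError(f"annotation for unknown node {node!r}")
        for key in pairs:
            if key not in ANNOTATION_KEYS:
                raise TreeValidationError(
                    f"annotation key {key!r} not in {ANNOTATION_KEYS}"
                )

    def render(node: str) -> str:
        kids = tree.children[node]
        inner = "(" + ",".join(render(k) for k in kids) + ")" if kids else ""
        name = _fmt_label(tree.label[node]) if node in tree.label else ""
        note = notes.get(node)
        comment = (
            "[&" + ",".join(f"{k}={_fmt_value(v)}" for k, v in sorted(note.items())) + "]"
            if note
            else ""
        )
        return inner + name + comment

    return render(tree.root) + ";"


def to_newick(tree: PhyloTree) -> str:
    """Plain newick of the topology and labels."""
    return write_annotated(tree, None)


def read_newick(path: str | io.TextIOBase) -> PhyloTree:
    """Read a newick tree from a file path or open text handle."""
    if hasattr(path, "read"):
        return parse_newick(path.read())
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_newick(fh.read())
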