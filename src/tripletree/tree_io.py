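"""Rooted binary trees in newick form, plus the shared taxon index.

All downstream machinery (bitset clades, the triplet-consistency dynamic
program) assumes every tree in a run is a *rooted binary* tree on exactly
the same taxon set.  This module is the single gatekeeper for that
assumption: parsing goes through dendropy, but every tree is converted to
a minimal in-house node structure and validated hard (binary, complete,
no duplicate leaves) before anything else sees it.

Taxon labels are mapped to bit positions ``0..n-1`` in lexicographic
order, so results never depend on file ordering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy


class TreeError(ValueError):
    """Raised for malformed, non-binary, or mislabelled input trees."""


class Node:
    """A node of a rooted tree.

    Leaves carry a ``label``; internal nodes have exactly two children
    (enforced at validation time, not construction time).
    """

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: Optional[str] = None) -> None:
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class TaxonIndex:
    """Canonical bijection between taxon labels and bit positions.

    Labels are stored sorted lexicographically; ``position[label]`` is the
    bit assigned to that taxon in every clade bitset of the run.
    """

    labels: tuple[str, ...]
    position: dict[str, int] = field(compare=False)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "TaxonIndex":
        uniq = sorted(set(labels))
        if len(uniq) != len(labels):
            dupes = sorted({x for x in labels if list(labels).count(x) > 1})
            raise TreeError(f"duplicate taxon labels: {dupes}")
        return cls(labels=tuple(uniq), position={t: i for i, t in enumerate(uniq)})

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)


class RootedTree:
    """A rooted binary tree over a :class:`TaxonIndex`."""

    def __init__(self, root: Node, index: TaxonIndex) -> None:
        self.root = root
        self.index = index

    def leaves(self) -> Iterator[Node]:
        for node in self.postorder():
            if node.is_leaf:
                yield node

    def postorder(self) -> Iterator[Node]:
        # Iterative: trees can be caterpillars deeper than the recursion limit.
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def internal_nodes(self) -> Iterator[Node]:
        for node in self.postorder():
            if not node.is_leaf:
                yield node

    @property
    def n(self) -> int:
        return self.index.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return self.index == other.index and write_newick(self) == write_newick(other)

    def __hash__(self) -> int:
        return hash(write_newick(self))


@dataclass
class GeneTreeSet:
    """k rooted binary gene trees, all on the same taxon set."""

    trees: list[RootedTree]
    taxon_index: TaxonIndex

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return self.taxon_index.n


def _convert(dnode: dendropy.Node) -> Node:
    """Convert a dendropy node (and its subtree) to the internal structure."""
    stack = [(dnode, None)]
    root = None
    while stack:
        dn, parent = stack.pop()
        if dn.is_leaf():
            if dn.taxon is None or not dn.taxon.label:
                raise TreeError("leaf without a label")
            node = Node(label=dn.taxon.label)
        else:
            node = Node()
        if parent is None:
            root = node
        else:
            parent.add_child(node)
        # reversed keeps original child order after stack pop
        for child in reversed(dn.child_nodes()):
            stack.append((child, node))
    assert root is not None
    return root


def _validate(root: Node, index: Optional[TaxonIndex]) -> TaxonIndex:
    labels: list[str] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            labels.append(node.label)  # type: ignore[arg-type]
        else:
            if len(node.children) != 2:
                raise TreeError(
                    f"non-binary tree: node with {len(node.children)} children "
                    "(rooted binary input required)"
                )
            stack.extend(node.children)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate leaf label(s): {dupes}")
    if index is None:
        return TaxonIndex.from_labels(labels)
    got, want = set(labels), set(index.labels)
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise TreeError(
            f"taxon set mismatch: missing {missing or '{}'}, unexpected {extra or '{}'}"
        )
    return index


def parse_newick(text: str, index: Optional[TaxonIndex] = None) -> RootedTree:
    """Parse one rooted binary tree from a newick string.

    Branch lengths, internal labels/support values and ``[...]`` comments
    are accepted and discarded — topology is all that is retained.  A root
    (or any node) with more than two children is rejected: the triplet
    criterion is root-dependent and unrooted/multifurcating input is out
    of scope.

    Parameters
    ----------
    text:
        A newick string terminated by ``;``.
    index:
        If given, the leaf set is validated against it; otherwise a new
        index is built from the leaves.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse error: {exc}") from None
    root = _convert(dtree.seed_node)
    idx = _validate(root, index)
    return RootedTree(root, idx)


def read_gene_trees(path) -> GeneTreeSet:
    """Read a newick file (one rooted binary tree per non-blank line).

    The taxon index is built from the first tree; every later tree must
    carry exactly the same taxon set.  Errors name the 1-based line.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
    else:
        with open(path) as fh:
            lines = fh.readlines()
    trees: list[RootedTree] = []
    index: Optional[TaxonIndex] = None
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            tree = parse_newick(line, index)
        except TreeError as exc:
            raise TreeError(f"line {lineno}: {exc}") from None
        if index is None:
            index = tree.index
        trees.append(tree)
    if not trees:
        raise TreeError("no trees found")
    assert index is not None
    return GeneTreeSet(trees=trees, taxon_index=index)


def write_newick(tree: RootedTree) -> str:
    """Serialize to newick without branch lengths, in canonical child order.

    At every internal node the child whose subtree contains the lowest
    taxon position is written first, so equal topologies always serialize
    to byte-identical strings.
    """
    pos = tree.index.position

    def min_pos(node: Node) -> int:
        best = len(pos)
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                best = min(best, pos[cur.label])  # type: ignore[index]
            else:
                stack.extend(cur.children)
        return best

    def render(node: Node) -> str:
        if node.is_leaf:
            return _quote_label(node.label)  # type: ignore[arg-type]
        kids = sorted(node.children, key=min_pos)
        return "(" + ",".join(render(c) for c in kids) + ")"

    # recursion depth: tree height < 2n; bump would be needed only for n in the
    # thousands, outside this package's scale
    return render(tree.root) + ";"


_NEWICK_UNSAFE = set("()[]{}:;,= \t\n'\"")


def _quote_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label
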