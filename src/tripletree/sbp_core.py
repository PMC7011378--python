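"""Subtree-bipartitions and closed-form triplet counting.

Every internal node ``u`` of a rooted binary tree splits the taxa of its
subtree into the leaf sets of its two children; that unordered pair of
disjoint clades is the node's *subtree-bipartition* (SBP).  Each rooted
triplet ``a|bc`` induced by the tree maps to exactly one SBP — the one at
the LCA of the three taxa, with the cherry ``{b,c}`` on one side and the
outlier ``a`` on the other.  This mapping turns triplet agreement between
trees into intersections of clade bitsets, so the triplet-consistency
score of a candidate split is computed in closed form without ever
enumerating the 3*C(n,3) triplets.

Clades are plain Python ints used as bitsets over the shared
:class:`~tripletree.tree_io.TaxonIndex`; all scores are exact integer
counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .tree_io import GeneTreeSet, Node, RootedTree, TaxonIndex

Clade = int  # bitset over the taxon index


def clade_of_labels(labels: Iterable[str], index: TaxonIndex) -> Clade:
    bits = 0
    for lab in labels:
        bits |= 1 << index.position[lab]
    return bits


def make_sbp(a: Clade, b: Clade) -> "SubtreeBipartition":
    """Build a canonical SBP from two disjoint nonempty clades."""
    if a == 0 or b == 0:
        raise ValueError("SBP sides must be nonempty")
    if a & b:
        raise ValueError("SBP sides must be disjoint")
    union = a | b
    low = union & -union  # lowest set bit of the union
    if low & a:
        return SubtreeBipartition(a, b)
    return SubtreeBipartition(b, a)


@dataclass(frozen=True)
class SubtreeBipartition:
    """Unordered pair of disjoint clades, stored in canonical order.

    ``left`` is the side containing the lowest set bit of the union, so
    equality and sorting are well-defined whatever the construction
    order.  Use :func:`make_sbp` rather than the constructor.
    """

    left: Clade
    right: Clade

    @property
    def union(self) -> Clade:
        return self.left | self.right

    def sort_key(self) -> tuple[int, int]:
        return (self.left, self.right)


@dataclass
class SBPMultiset:
    """Subtree-bipartitions pooled over all gene trees, with multiplicity.

    Scoring (the gene-tree side of the triplet-consistency score) uses
    the multiset; the constrained search space uses only ``distinct``.
    """

    counts: Counter = field(default_factory=Counter)
    index: TaxonIndex | None = None

    @property
    def distinct(self) -> list[SubtreeBipartition]:
        return sorted(self.counts, key=SubtreeBipartition.sort_key)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def extract_sbps(tree: RootedTree, index: TaxonIndex) -> list[SubtreeBipartition]:
    """One SBP per internal node (the root included), via one post-order pass.

    A binary tree on n taxa yields exactly n-1 SBPs.
    """
    pos = index.position
    clade: dict[int, Clade] = {}
    sbps: list[SubtreeBipartition] = []
    for node in tree.postorder():
        if node.is_leaf:
            clade[id(node)] = 1 << pos[node.label]  # type: ignore[index]
        else:
            a = clade[id(node.children[0])]
            b = clade[id(node.children[1])]
            clade[id(node)] = a | b
            sbps.append(make_sbp(a, b))
    return sbps


def pool_sbps(genes: GeneTreeSet) -> SBPMultiset:
    """Multiset union of SBPs over all gene trees (multiplicities kept)."""
    pool = SBPMultiset(index=genes.taxon_index)
    for tree in genes.trees:
        pool.counts.update(extract_sbps(tree, genes.taxon_index))
    return pool


def nt_count(n1: int, n2: int) -> int:
    """Number of triplets mapped to an SBP with side sizes n1, n2.

    A mapped triplet takes its cherry from one side and its outlier from
    the other: C(n1,2)*n2 + C(n2,2)*n1 = n1*n2*(n1+n2-2)/2.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("side sizes must be non-negative")
    return n1 * n2 * (n1 + n2 - 2) // 2


def shared_triplets(x: SubtreeBipartition, y: SubtreeBipartition) -> int:
    """Number of triplets mapped to both x and y.

    The shared triplets live in the pairwise side intersections; each is
    counted exactly once because a triplet's cherry and outlier land in
    one intersection pair only.
    """
    return nt_count((x.left & y.left).bit_count(), (x.right & y.right).bit_count()) + nt_count(
        (x.left & y.right).bit_count(), (x.right & y.left).bit_count()
    )


def tc_score_sbp(x: SubtreeBipartition, pool: SBPMultiset) -> int:
    """Total triplets over all gene trees mapped to x and agreeing with them."""
    return sum(mult * shared_triplets(x, y) for y, mult in pool.counts.items())


def tc_score_tree(species: RootedTree, genes: GeneTreeSet) -> int:
    """Triplet-consistency score of a species tree against a gene-tree set.

    Sums the per-SBP score over the species tree's n-1 subtree-bipartitions;
    equals the brute-force count of (gene tree, 3-subset) pairs whose
    induced triplets agree, and is bounded by k*C(n,3).
    """
    if set(l.label for l in species.leaves()) != set(genes.taxon_index.labels):
        raise ValueError("species tree and gene trees are on different taxon sets")
    pool = pool_sbps(genes)
    return sum(tc_score_sbp(x, pool) for x in extract_sbps(species, genes.taxon_index))
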