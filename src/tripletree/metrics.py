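"""Tree comparison: induced triplets, a brute-force agreement oracle, and
Robinson-Foulds rates.

``triplet_oracle`` is deliberately naive — it restricts trees to every
3-subset by LCA depth comparison and counts agreements one subset at a
time.  It shares no code with the closed-form bitset scoring, which makes
it the independent ground truth those counts are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tree_io import GeneTreeSet, Node, RootedTree


@dataclass(frozen=True)
class TripletTopology:
    """A rooted 3-taxon topology: the outlier vs. the cherry pair."""

    taxa: frozenset[str]
    outlier: str

    def __post_init__(self) -> None:
        if len(self.taxa) != 3 or self.outlier not in self.taxa:
            raise ValueError("need 3 distinct taxa with the outlier among them")


def _depths_and_parents(tree: RootedTree) -> tuple[dict[int, int], dict[str, Node]]:
    depth: dict[int, int] = {id(tree.root): 0}
    by_label: dict[str, Node] = {}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            by_label[node.label] = node  # type: ignore[index]
        for child in node.children:
            depth[id(child)] = depth[id(node)] + 1
            stack.append(child)
    return depth, by_label


def _lca_depth(a: Node, b: Node, depth: dict[int, int]) -> int:
    da, db = depth[id(a)], depth[id(b)]
    while da > db:
        a = a.parent  # type: ignore[assignment]
        da -= 1
    while db > da:
        b = b.parent  # type: ignore[assignment]
        db -= 1
    while a is not b:
        a, b = a.parent, b.parent  # type: ignore[assignment]
        da -= 1
    return da


def induced_triplet(tree: RootedTree, taxa) -> TripletTopology:
    """The rooted topology ``tree`` induces on a 3-subset of its leaves.

    The pair whose LCA lies strictly below the LCA of all three is the
    cherry; the remaining taxon is the outlier.
    """
    labels = sorted(taxa)
    if len(set(labels)) != 3:
        raise ValueError("need exactly 3 distinct taxa")
    depth, by_label = _depths_and_parents(tree)
    try:
        nodes = [by_label[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(f"taxon {exc.args[0]!r} not in tree") from None
    a, b, c = nodes
    dab = _lca_depth(a, b, depth)
    dac = _lca_depth(a, c, depth)
    dbc = _lca_depth(b, c, depth)
    # the deepest pairwise LCA identifies the cherry; in a binary tree
    # exactly one pair is strictly deeper than the overall LCA
    if dab > dac and dab > dbc:
        outlier = labels[2]
    elif dac > dab and dac > dbc:
        outlier = labels[1]
    else:
        outlier = labels[0]
    return TripletTopology(taxa=frozenset(labels), outlier=outlier)


def all_induced_triplets(tree: RootedTree) -> dict[frozenset, str]:
    """Outlier for every 3-subset, with depths computed once."""
    from itertools import combinations

    depth, by_label = _depths_and_parents(tree)
    out: dict[frozenset, str] = {}
    labels = sorted(by_label)
    for la, lb, lc in combinations(labels, 3):
        a, b, c = by_label[la], by_label[lb], by_label[lc]
        dab = _lca_depth(a, b, depth)
        dac = _lca_depth(a, c, depth)
        dbc = _lca_depth(b, c, depth)
        if dab > dac and dab > dbc:
            outlier = lc
        elif dac > dab and dac > dbc:
            outlier = lb
        else:
            outlier = la
        out[frozenset((la, lb, lc))] = outlier
    return out


def triplet_oracle(species: RootedTree, genes: GeneTreeSet) -> int:
    """Brute-force triplet agreement count between a species tree and gene trees.

    For every 3-subset and every gene tree, add 1 if the induced rooted
    topologies match.  O(k n^3); testing ground truth only — the main
    inference path never enumerates triplets.
    """
    species_labels = {l.label for l in species.leaves()}
    if species_labels != set(genes.taxon_index.labels):
        raise ValueError("species tree and gene trees are on different taxon sets")
    ref = all_induced_triplets(species)
    total = 0
    for gt in genes.trees:
        induced = all_induced_triplets(gt)
        total += sum(1 for key, outlier in ref.items() if induced[key] == outlier)
    return total


def _clades(tree: RootedTree) -> dict[int, int]:
    """Bitset clade per node id (over the tree's taxon index)."""
    pos = tree.index.position
    clade: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clade[id(node)] = 1 << pos[node.label]  # type: ignore[index]
        else:
            bits = 0
            for child in node.children:
                bits |= clade[id(child)]
            clade[id(node)] = bits
    return clade


def _unrooted_bipartitions(tree: RootedTree) -> set[int]:
    n = tree.index.n
    full = (1 << n) - 1
    clade = _clades(tree)
    splits: set[int] = set()
    for node in tree.internal_nodes():
        if node is tree.root:
            continue
        bits = clade[id(node)]
        if 2 <= bits.bit_count() <= n - 2:
            # canonical side: the one not containing taxon 0
            splits.add(bits if not (bits & 1) else full ^ bits)
    return splits


def _rooted_clades(tree: RootedTree) -> set[int]:
    clade = _clades(tree)
    return {
        clade[id(node)]
        for node in tree.internal_nodes()
        if node is not tree.root
    }


def rf_rate(t1: RootedTree, t2: RootedTree, rooted: bool = False) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    Default convention treats both trees as unrooted: the symmetric
    difference of the n-3 non-trivial bipartitions of each, normalized by
    2(n-3).  With ``rooted=True`` the comparison is over non-root clades,
    normalized by 2(n-2) — appropriate when rooting itself is part of the
    estimate.  Both are 0 exactly for identical topologies under their
    convention.
    """
    if set(t1.index.labels) != set(t2.index.labels):
        raise ValueError("trees are on different taxon sets")
    n = t1.index.n
    if rooted:
        if n < 3:
            raise ValueError("rooted RF needs n >= 3")
        a, b = _rooted_clades(t1), _rooted_clades(t2)
        denom = 2 * (n - 2)
    else:
        if n < 4:
            raise ValueError(
                "unrooted RF is undefined for n < 4 (no non-trivial splits); "
                "use rooted=True"
            )
        a, b = _unrooted_bipartitions(t1), _unrooted_bipartitions(t2)
        denom = 2 * (n - 3)
    return len(a ^ b) / denom
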