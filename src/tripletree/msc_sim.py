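"""Gene-tree simulation under the multi-species coalescent (MSC).

The species tree carries branch lengths in coalescent units (generations
divided by effective population size).  One haploid lineage enters at
each species tip; within a branch of length t currently holding j
lineages the waiting time to the next coalescence is exponential with
rate j(j-1)/2, and an event merges a uniformly chosen pair.  Lineages
that fail to coalesce before the top of the branch pass into the parent
branch; above the root coalescence continues until a single lineage
remains.  Discordance between the gene trees and the species tree is
exactly incomplete lineage sorting: the shorter an internal branch, the
likelier two lineages escape it and sort randomly deeper in the tree.

For a three-taxon species tree ((A,B),C) with internal branch t this
yields the classic matching-triplet probability 1 - (2/3)e^(-t), which
the test suite checks against this simulator.

Only the gene-tree *topology* is retained downstream: the inference
criterion is topology-only, so coalescence times are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .tree_io import GeneTreeSet, Node, RootedTree, TaxonIndex, write_newick


@dataclass
class MSCSpeciesTree:
    """A rooted binary species tree with coalescent-unit branch lengths.

    ``lengths`` maps ``id(node)`` to the length of the branch above that
    node; the root's branch is conceptually infinite and needs no entry.
    """

    tree: RootedTree
    lengths: dict[int, float]

    def __post_init__(self) -> None:
        for node in self.tree.postorder():
            if node is self.tree.root:
                continue
            t = self.lengths.get(id(node))
            if t is None or not (t > 0) or not np.isfinite(t):
                raise ValueError("every non-root branch needs a positive finite length")


@dataclass
class SimConfig:
    species_tree: MSCSpeciesTree
    n_genes: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def _coalesce_in_branch(
    lineages: list[Node], t: float, rng: np.random.Generator
) -> list[Node]:
    """Run the coalescent among ``lineages`` for time t (inf for the root stem)."""
    lineages = list(lineages)
    elapsed = 0.0
    while len(lineages) > 1:
        j = len(lineages)
        wait = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        elapsed += wait
        if elapsed > t:
            break
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = lineages[i1], lineages[i2]
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        keep = [x for idx, x in enumerate(lineages) if idx not in (i1, i2)]
        keep.append(parent)
        lineages = keep
    return lineages


def simulate_gene_tree(species: MSCSpeciesTree, rng: np.random.Generator) -> RootedTree:
    """Draw one gene-tree topology under the MSC within ``species``."""
    pending: dict[int, list[Node]] = {}
    for node in species.tree.postorder():
        if node.is_leaf:
            lineages = [Node(label=node.label)]
        else:
            lineages = pending.pop(id(node.children[0])) + pending.pop(id(node.children[1]))
        if node is species.tree.root:
            survivors = _coalesce_in_branch(lineages, float("inf"), rng)
            assert len(survivors) == 1
            return RootedTree(survivors[0], species.tree.index)
        pending[id(node)] = _coalesce_in_branch(lineages, species.lengths[id(node)], rng)
    raise AssertionError("unreachable")


def simulate_gene_trees(config: SimConfig) -> GeneTreeSet:
    """n_genes independent MSC draws; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    trees = [simulate_gene_tree(config.species_tree, rng) for _ in range(config.n_genes)]
    return GeneTreeSet(trees=trees, taxon_index=config.species_tree.tree.index)


Shape = Literal["caterpillar", "balanced", "random_yule"]

_PENDANT_LENGTH = 1.0  # irrelevant with one sampled lineage per species


def make_model_tree(
    shape: Shape,
    n: int,
    internal_bl: float,
    rescale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> MSCSpeciesTree:
    """Build a model species tree with uniform internal branch lengths.

    All internal branches get ``internal_bl * rescale`` coalescent units;
    halving the product doubles the opportunity for incomplete lineage
    sorting, which is how ILS level is dialled in simulation studies.
    Pendant branch lengths are inert here (one lineage per species cannot
    coalesce with itself) and are set to a nominal constant.

    ``caterpillar`` and ``balanced`` are deterministic; ``random_yule``
    grows a topology by repeatedly splitting a uniformly chosen tip and
    needs ``rng``.
    """
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if internal_bl <= 0 or rescale <= 0:
        raise ValueError("internal_bl and rescale must be positive")
    labels = [f"t{i + 1}" for i in range(n)]
    index = TaxonIndex.from_labels(labels)

    if shape == "caterpillar":
        root = _caterpillar(labels)
    elif shape == "balanced":
        root = _balanced(labels)
    elif shape == "random_yule":
        if rng is None:
            raise ValueError("random_yule needs an rng")
        root = _yule(labels, rng)
    else:
        raise ValueError(f"unknown shape {shape!r}")

    tree = RootedTree(root, index)
    bl = internal_bl * rescale
    lengths: dict[int, float] = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        lengths[id(node)] = _PENDANT_LENGTH if node.is_leaf else bl
    return MSCSpeciesTree(tree=tree, lengths=lengths)


def _caterpillar(labels: list[str]) -> Node:
    # ((...(t1,t2),t3)...,tn)
    node = Node(label=labels[0])
    for lab in labels[1:]:
        parent = Node()
        parent.add_child(node)
        parent.add_child(Node(label=lab))
        node = parent
    return node


def _balanced(labels: list[str]) -> Node:
    if len(labels) == 1:
        return Node(label=labels[0])
    mid = (len(labels) + 1) // 2
    parent = Node()
    parent.add_child(_balanced(labels[:mid]))
    parent.add_child(_balanced(labels[mid:]))
    return parent


def _yule(labels: list[str], rng: np.random.Generator) -> Node:
    order = list(rng.permutation(len(labels)))
    tips: list[Node] = [Node(label=labels[order[0]])]
    root = tips[0]
    for idx in order[1:]:
        victim = tips[int(rng.integers(len(tips)))]
        # split the chosen tip: it becomes internal with the old leaf and
        # the new one as children
        old = Node(label=victim.label)
        new = Node(label=labels[idx])
        victim.label = None
        victim.add_child(old)
        victim.add_child(new)
        tips.remove(victim)
        tips.extend([old, new])
    return root


def random_topology(n: int, rng: np.random.Generator) -> RootedTree:
    """Uniform-ish random rooted binary topology on n generic labels (Yule).

    Convenience for property tests and random-instance sweeps.
    """
    model = make_model_tree("random_yule", n, internal_bl=1.0, rng=rng)
    return model.tree


def write_simulation(genes: GeneTreeSet, config_record: dict, tree_path, sidecar_path) -> None:
    """Write one newick line per gene tree plus a JSON config sidecar."""
    with open(tree_path, "w") as fh:
        for tree in genes.trees:
            fh.write(write_newick(tree) + "\n")
    with open(sidecar_path, "w") as fh:
        json.dump(config_record, fh, indent=2, sort_keys=True)
        fh.write("\n")
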