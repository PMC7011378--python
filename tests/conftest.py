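"""Shared fixtures and oracle helpers.

``enumerate_rooted_topologies`` and ``random_instance`` are test-side
machinery: exhaustive/brute-force ground truth that stays independent of
the bitset scoring and the DP under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from tripletree.tree_io import GeneTreeSet, Node, RootedTree, TaxonIndex
from tripletree.msc_sim import random_topology


def tuple_to_tree(top, index: TaxonIndex) -> RootedTree:
    """Convert a nested-tuple topology (leaves are label strings) to a tree."""

    def build(t):
        if isinstance(t, str):
            return Node(label=t)
        node = Node()
        node.add_child(build(t[0]))
        node.add_child(build(t[1]))
        return node

    return RootedTree(build(top), index)


def enumerate_rooted_topologies(labels: list[str]):
    """All (2n-3)!! rooted binary topologies on ``labels`` as nested tuples.

    Grown by inserting each successive label on every branch (including
    above the root) of every smaller topology.
    """
    tops = [labels[0]]
    for lab in labels[1:]:
        grown = []
        for top in tops:
            grown.extend(_insert_everywhere(top, lab))
        tops = grown
    return tops


def _insert_everywhere(top, lab):
    # attach above the current (sub)tree root
    yield (top, lab)
    if not isinstance(top, str):
        left, right = top
        for new_left in _insert_everywhere(left, lab):
            yield (new_left, right)
        for new_right in _insert_everywhere(right, lab):
            yield (left, new_right)


def random_instance(rng: np.random.Generator, n: int, k: int) -> tuple[RootedTree, GeneTreeSet]:
    """A random species tree plus k independent random gene trees on n taxa."""
    species = random_topology(n, rng)
    genes = [random_topology(n, rng) for _ in range(k)]
    # rebuild gene trees on the species tree's index so label/bit mapping is shared
    return species, GeneTreeSet(trees=genes, taxon_index=species.index)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
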