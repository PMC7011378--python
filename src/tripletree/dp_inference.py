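"""Dynamic program maximizing triplet consistency over clusters.

The optimization asks for the rooted binary species tree whose induced
triplets agree with as many (gene tree, 3-subset) pairs as possible,
subject to every subtree-bipartition of the output lying in a given set:
either the SBPs observed in the gene trees (*constrained* mode, the
default heuristic) or all possible bipartitions (*exact* mode, a full
subset DP that is exponential in n and guarded by a taxon cap).

Let V(A) be the best achievable score of a subtree on cluster A:

    V(A) = 0 for |A| = 1
    V(A) = max over admissible splits A'|A-A' of
           V(A') + V(A-A') + TC(A'|A-A')

where TC(x) is the pooled triplet agreement of split x with the gene
trees.  Backtracking from the full taxon set yields the species tree.
Ties in the max are broken by canonical SBP order (smallest left-clade
bitset, then right), so runs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from .sbp_core import (
    SBPMultiset,
    SubtreeBipartition,
    extract_sbps,
    make_sbp,
    pool_sbps,
    tc_score_sbp,
)
from .tree_io import GeneTreeSet, Node, RootedTree, TaxonIndex

logger = logging.getLogger(__name__)

Mode = Literal["constrained", "exact"]

DEFAULT_EXACT_CAP = 15


class ExactCapError(ValueError):
    """Exact mode refused: the all-subsets DP is exponential in n."""


@dataclass
class SearchSpace:
    mode: Mode
    index: TaxonIndex
    # constrained mode only: cluster bitset -> candidate splits of that cluster
    candidate_splits: dict[int, list[SubtreeBipartition]]
    pool: SBPMultiset


@dataclass
class DPResult:
    V: dict[int, int]
    backpointer: dict[int, SubtreeBipartition]
    species_tree: RootedTree
    total_score: int
    mode: Mode


def build_search_space(
    pool: SBPMultiset,
    mode: Mode = "constrained",
    index: TaxonIndex | None = None,
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> SearchSpace:
    """Assemble the cluster/split structure the DP will search.

    Constrained mode indexes the distinct gene-tree SBPs by their union
    cluster.  Exact mode keeps nothing: splits are generated lazily per
    cluster during the DP (materializing all 2^(n-1)-1 splits of every
    subset would be hopeless), but refuses to start above ``exact_cap``
    taxa because the subset DP costs Theta(3^n) split evaluations.
    """
    if index is None:
        index = pool.index
    if index is None:
        raise ValueError("a TaxonIndex is required")
    n = index.n
    if mode == "exact":
        if n > exact_cap:
            raise ExactCapError(
                f"exact mode on n={n} taxa exceeds the cap ({exact_cap}): "
                "the all-subsets search is exponential; raise exact_cap "
                "explicitly if you really mean it"
            )
        return SearchSpace(mode="exact", index=index, candidate_splits={}, pool=pool)
    full = (1 << n) - 1
    splits: dict[int, list[SubtreeBipartition]] = {}
    for sbp in pool.distinct:
        splits.setdefault(sbp.union, []).append(sbp)
    if full not in splits:
        raise ValueError(
            "no gene tree spans the full taxon set at its root; constrained "
            "mode needs complete gene trees"
        )
    for cands in splits.values():
        cands.sort(key=SubtreeBipartition.sort_key)
    return SearchSpace(mode="constrained", index=index, candidate_splits=splits, pool=pool)


def _splits_of(cluster: int, space: SearchSpace) -> list[SubtreeBipartition]:
    if space.mode == "constrained":
        return space.candidate_splits.get(cluster, [])
    # exact: every bipartition of the cluster, canonically ordered.  Fixing
    # the cluster's lowest bit on the left enumerates each unordered pair once.
    low = cluster & -cluster
    rest = cluster ^ low
    out = []
    sub = rest
    while True:
        left = low | sub
        right = cluster ^ left
        if right:
            out.append(make_sbp(left, right))
        if sub == 0:
            break
        sub = (sub - 1) & rest
    out.sort(key=SubtreeBipartition.sort_key)
    return out


def solve(space: SearchSpace, pool: SBPMultiset | None = None) -> DPResult:
    """Run the cluster DP and reconstruct the optimal species tree."""
    if pool is None:
        pool = space.pool
    index = space.index
    n = index.n
    full = (1 << n) - 1

    tc_cache: dict[SubtreeBipartition, int] = {}

    def tc(x: SubtreeBipartition) -> int:
        val = tc_cache.get(x)
        if val is None:
            val = tc_cache[x] = tc_score_sbp(x, pool)
        return val

    V: dict[int, int] = {1 << i: 0 for i in range(n)}
    back: dict[int, SubtreeBipartition] = {}

    if space.mode == "constrained":
        clusters = sorted(space.candidate_splits, key=lambda c: (c.bit_count(), c))
    else:
        # every nonempty subset, by increasing size
        clusters = sorted(
            (c for c in range(1, full + 1) if c.bit_count() >= 2),
            key=lambda c: (c.bit_count(), c),
        )
    for cluster in clusters:
        if cluster in V:
            continue
        best = None
        best_split = None
        for sbp in _splits_of(cluster, space):
            # both sides are themselves clusters (singletons or child SBP
            # unions in the same gene tree), so V is already final for them
            va = V.get(sbp.left)
            vb = V.get(sbp.right)
            assert va is not None and vb is not None, "unreachable side cluster"
            score = va + vb + tc(sbp)
            if best is None or score > best:
                best, best_split = score, sbp
        assert best is not None and best_split is not None, "cluster with no split"
        V[cluster] = best
        back[cluster] = best_split

    if full not in V:
        raise ValueError("full taxon set unreachable in the search space")

    root = _backtrack(full, back, index)
    return DPResult(
        V=V,
        backpointer=back,
        species_tree=RootedTree(root, index),
        total_score=V[full],
        mode=space.mode,
    )


def _backtrack(cluster: int, back: dict[int, SubtreeBipartition], index: TaxonIndex) -> Node:
    if cluster.bit_count() == 1:
        return Node(label=index.labels[cluster.bit_length() - 1])
    sbp = back[cluster]
    node = Node()
    node.add_child(_backtrack(sbp.left, back, index))
    node.add_child(_backtrack(sbp.right, back, index))
    return node


def infer(
    genes: GeneTreeSet,
    mode: Mode = "constrained",
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> DPResult:
    """Pool SBPs, build the search space, solve, and log the run shape."""
    pool = pool_sbps(genes)
    space = build_search_space(pool, mode=mode, index=genes.taxon_index, exact_cap=exact_cap)
    result = solve(space, pool)
    logger.info(
        "inference: n=%d k=%d distinct_sbp=%d mode=%s score=%d",
        genes.n,
        genes.k,
        len(pool.counts),
        mode,
        result.total_score,
    )
    return result
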