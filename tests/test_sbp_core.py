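from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripletree.tree_io import GeneTreeSet, TaxonIndex, parse_newick
from tripletree.sbp_core import (
    clade_of_labels,
    extract_sbps,
    make_sbp,
    nt_count,
    pool_sbps,
    shared_triplets,
    tc_score_sbp,
    tc_score_tree,
)
from tripletree.metrics import triplet_oracle
from conftest import random_instance


def sbp_from_labels(left, right, index):
    return make_sbp(clade_of_labels(left, index), clade_of_labels(right, index))


IDX3 = TaxonIndex.from_labels(["a", "b", "c"])


class TestExtractSbps:
    def test_three_taxon_tree(self):
        tree = parse_newick("((a,b),c);", IDX3)
        got = set(extract_sbps(tree, IDX3))
        want = {sbp_from_labels({"a"}, {"b"}, IDX3), sbp_from_labels({"a", "b"}, {"c"}, IDX3)}
        assert got == want

    def test_caterpillar_four(self):
        idx = TaxonIndex.from_labels(list("abcd"))
        tree = parse_newick("(((a,b),c),d);", idx)
        got = set(extract_sbps(tree, idx))
        want = {
            sbp_from_labels({"a"}, {"b"}, idx),
            sbp_from_labels({"a", "b"}, {"c"}, idx),
            sbp_from_labels({"a", "b", "c"}, {"d"}, idx),
        }
        assert got == want

    def test_count_is_n_minus_one(self, rng):
        for n in range(3, 12):
            from tripletree.msc_sim import random_topology

            t = random_topology(n, rng)
            assert len(extract_sbps(t, t.index)) == n - 1


class TestPoolSbps:
    def test_multiplicities_preserved(self):
        t = parse_newick("((a,b),c);", IDX3)
        pool = pool_sbps(GeneTreeSet([t, t, t], IDX3))
        assert pool.total == 3 * 2
        assert set(pool.counts.values()) == {3}
        assert len(pool.distinct) == 2

    def test_distinct_trees_distinct_sbps(self):
        g1 = parse_newick("((a,b),c);", IDX3)
        g2 = parse_newick("((b,c),a);", IDX3)
        pool = pool_sbps(GeneTreeSet([g1, g2], IDX3))
        assert len(pool.distinct) == 4
        assert all(m == 1 for m in pool.counts.values())

    def test_total_multiplicity_k_times_n_minus_1(self, rng):
        _, genes = random_instance(rng, n=8, k=5)
        assert pool_sbps(genes).total == 5 * 7


def brute_force_nt(n1, n2):
    """Enumerate all 3-subsets of two disjoint sides; count 2+1 mixes."""
    side1 = [("L", i) for i in range(n1)]
    side2 = [("R", i) for i in range(n2)]
    total = 0
    for trio in combinations(side1 + side2, 3):
        sides = [s for s, _ in trio]
        if sides.count("L") in (1, 2):
            total += 1
    return total


class TestNtCount:
    @pytest.mark.parametrize("n1,n2,expected", [(1, 1, 0), (2, 1, 1), (3, 2, 9), (0, 5, 0)])
    def test_known_values(self, n1, n2, expected):
        assert nt_count(n1, n2) == expected

    @given(st.integers(0, 8), st.integers(0, 8))
    @settings(derandomize=True, deadline=None)
    def test_matches_enumeration(self, n1, n2):
        assert nt_count(n1, n2) == brute_force_nt(n1, n2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            nt_count(-1, 2)


class TestSharedTriplets:
    def test_identical_sbp(self):
        x = sbp_from_labels({"a", "b"}, {"c"}, IDX3)
        assert shared_triplets(x, x) == 1
        assert shared_triplets(x, x) == nt_count(2, 1)

    def test_conflicting_splits_share_nothing(self):
        idx = TaxonIndex.from_labels(list("abcd"))
        x = sbp_from_labels({"a", "b"}, {"c", "d"}, idx)
        y = sbp_from_labels({"a", "c"}, {"b", "d"}, idx)
        assert shared_triplets(x, y) == 0

    def test_disjoint_supports(self):
        idx = TaxonIndex.from_labels(list("abcdef"))
        x = sbp_from_labels({"a", "b"}, {"c"}, idx)
        y = sbp_from_labels({"d", "e"}, {"f"}, idx)
        assert shared_triplets(x, y) == 0

    def test_symmetry_on_random_sbps(self, rng):
        n = 10

        def random_sbp():
            while True:
                a = int(rng.integers(1, 2**n))
                b = int(rng.integers(1, 2**n)) & ~a
                if b:
                    return make_sbp(a, b)

        for _ in range(200):
            x, y = random_sbp(), random_sbp()
            assert shared_triplets(x, y) == shared_triplets(y, x)


class TestTcScores:
    def test_sbp_score_against_pool(self):
        t = parse_newick("((a,b),c);", IDX3)
        pool = pool_sbps(GeneTreeSet([t, t, t], IDX3))
        assert tc_score_sbp(sbp_from_labels({"a", "b"}, {"c"}, IDX3), pool) == 3
        assert tc_score_sbp(sbp_from_labels({"a", "c"}, {"b"}, IDX3), pool) == 0

    def test_tree_score_self_is_choose3(self):
        idx = TaxonIndex.from_labels(list("abcde"))
        t = parse_newick("((((a,b),c),d),e);", idx)
        assert tc_score_tree(t, GeneTreeSet([t], idx)) == comb(5, 3)

    def test_tree_score_majority_example(self):
        g1 = parse_newick("((b,c),a);", IDX3)
        g2 = parse_newick("((b,c),a);", IDX3)
        g3 = parse_newick("((a,c),b);", IDX3)
        genes = GeneTreeSet([g1, g2, g3], IDX3)
        assert tc_score_tree(parse_newick("((b,c),a);", IDX3), genes) == 2

    def test_identical_gene_trees_scale_linearly(self, rng):
        from tripletree.msc_sim import random_topology

        t = random_topology(8, rng)
        for k in (1, 4, 9):
            genes = GeneTreeSet([t] * k, t.index)
            assert tc_score_tree(t, genes) == k * comb(8, 3)

    def test_taxon_mismatch_rejected(self):
        t = parse_newick("((a,b),d);")
        genes = GeneTreeSet([parse_newick("((a,b),c);", IDX3)], IDX3)
        with pytest.raises(ValueError):
            tc_score_tree(t, genes)


class TestInvariants:
    def test_triplet_conservation_per_tree(self, rng):
        """Every triplet maps to exactly one SBP (its LCA node), so the
        per-SBP counts over one tree sum to C(n,3)."""
        from tripletree.msc_sim import random_topology

        for _ in range(30):
            n = int(rng.integers(3, 13))
            t = random_topology(n, rng)
            total = sum(
                nt_count(s.left.bit_count(), s.right.bit_count())
                for s in extract_sbps(t, t.index)
            )
            assert total == comb(n, 3)

    def test_oracle_equivalence(self, rng):
        """Closed-form bitset scoring equals brute-force triplet counting."""
        for _ in range(40):
            n = int(rng.integers(4, 11))
            k = int(rng.integers(1, 11))
            species, genes = random_instance(rng, n, k)
            assert tc_score_tree(species, genes) == triplet_oracle(species, genes)

    def test_score_bounds(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(4, 10)), int(rng.integers(1, 8))
            species, genes = random_instance(rng, n, k)
            s = tc_score_tree(species, genes)
            assert 0 <= s <= k * comb(n, 3)
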