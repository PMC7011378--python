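# Methods

## Model and estimation criterion

`tripletree` estimates a rooted species tree from a set of k rooted,
binary, single-copy gene trees on a common set of n species, under the
assumption that gene-tree/species-tree discordance is generated by the
multi-species coalescent (MSC), i.e. by incomplete lineage sorting.
Under the MSC, for any three species the rooted triplet topology matching
the species tree has probability strictly greater than 1/3, and the two
alternatives have equal, smaller probability — there is no rooted
three-taxon anomaly zone. Maximizing total triplet agreement with the
gene trees is therefore a consistent criterion: as the number of true
gene trees grows, the maximizer converges to the true species-tree
topology. The guarantee does not extend to discordance caused by gene
duplication/loss, horizontal transfer, or intra-locus recombination, and
the package makes no attempt to model those processes.

The criterion is evaluated without triplet enumeration. Each internal
node of a rooted binary tree contributes a subtree-bipartition (SBP): the
pair of its children's leaf sets. A triplet maps to exactly one SBP (at
the LCA of its three taxa), which gives the closed forms

* NT(n₁,n₂) = n₁n₂(n₁+n₂−2)/2 triplets mapped to an SBP with side sizes
  n₁, n₂, and
* M(x,y) = NT(|X₁∩Y₁|,|X₂∩Y₂|) + NT(|X₁∩Y₂|,|X₂∩Y₁|) triplets mapped to
  both of two SBPs,

evaluated on clade bitsets (Python ints; all scores are exact integers).
The per-tree conservation identity Σ_SBP NT = C(n,3) is a test invariant.
Scoring sums over the gene-tree SBP *multiset* (multiplicities kept);
the constrained search space uses only the distinct SBPs. The root
node's SBP is included in extraction and scoring — triplets whose LCA is
the root would otherwise be dropped and the conservation identity would
fail.

## Dynamic program

V(A) is the best score of a rooted subtree on cluster A:
V = 0 on singletons, and V(A) = max over admissible splits A′|A−A′ of
V(A′) + V(A−A′) + TC(A′|A−A′). Clusters are processed in increasing
cardinality, so both sides of any candidate split are final when
consumed; in constrained mode both sides of a gene-tree SBP are
themselves singletons or SBP unions from the same gene tree, so the DP
can never reach a dead cluster. Per-split TC values are cached, keeping
constrained mode at O(n²k|SBP|²).

Numerical/determinism choices:

* **Tie-breaking.** Candidate splits are scanned in canonical SBP order
  (ascending (left, right) bitset pair, where "left" holds the lowest
  bit of the union) with a strict `>` update, so the argmax is the
  canonically smallest maximizer. Identical input therefore yields
  byte-identical output; the choice is ours and is not claimed to match
  any other implementation's tie-breaking.
* **Exact mode** enumerates all 2^(|A|−1)−1 splits of every cluster
  lazily (never materialized globally). The subset DP costs Θ(3ⁿ) split
  evaluations, so it refuses above `exact_cap` (default 15 taxa, chosen
  as the point where ~1.4×10⁷ split evaluations remain tractable on one
  CPU; overridable).
* **Canonical serialization.** Newick output orders children by lowest
  contained taxon position; taxon-to-bit assignment is lexicographic in
  the labels, so nothing depends on input file order.
* **Degenerate inputs.** Multifurcations (including a trifurcating root,
  i.e. unrooted-style newick), duplicate leaf labels, and gene trees
  with missing taxa are rejected up front with line-numbered errors:
  the triplet criterion is root-dependent and the method is defined on
  complete rooted binary trees only. A single gene tree is valid input
  and is returned unchanged by inference.

## MSC simulator

The simulator draws gene-tree topologies down a species tree whose
branch lengths are in coalescent units (generations / effective
population size), one haploid lineage per species. Within a branch of
length t holding j lineages, waiting times are exponential with rate
j(j−1)/2 and a uniformly random pair merges per event; survivors pass to
the parent branch, and the stem above the root runs until one lineage
remains. Coalescence times are discarded: inference is topology-only.
Pendant branch lengths are inert with one lineage per species and are
set to a nominal 1.0.

`make_model_tree` provides deterministic caterpillar and balanced shapes
and a seeded Yule (random tip-splitting) topology, with every internal
branch set to `internal_bl · rescale` coalescent units — halving the
product increases ILS, doubling suppresses it, which is how simulation
studies dial discordance. Defaults used throughout the acceptance
pipeline: a 15-taxon caterpillar with internal branches of 0.5
coalescent units and 1000 gene trees, a substantial-ILS regime in which
individual gene trees are mostly discordant with the species tree but
the pooled triplet signal is decisive.

Calibration: for the 3-taxon tree ((A,B),C) with internal branch t, the
probability that a gene tree matches the species-tree triplet is
1 − (2/3)e^(−t). The test suite checks simulated frequencies against
this closed form within 3 binomial standard errors at 50,000 genes for
t ∈ {0.1, 0.5, 1, 2}, and checks that the two minority topologies are
statistically indistinguishable in frequency.

What the simulator does *not* emulate: sequence evolution and gene-tree
estimation error (gene trees are true MSC draws), missing taxa, multiple
samples per species, duplication/loss/transfer, and recombination.
Passing tests therefore demonstrate correctness of the estimator on
error-free gene trees; on real data, gene-tree estimation error degrades
all summary methods and is outside this package's scope.

## Metrics

`triplet_oracle` is the deliberately naive ground truth: it restricts
the two trees to every 3-subset via LCA depth comparisons and counts
agreements subset by subset, sharing no code with the bitset scoring it
validates. `rf_rate` reports the normalized Robinson-Foulds distance;
the default treats both trees as unrooted (symmetric difference of the
n−3 non-trivial bipartitions, normalized by 2(n−3)), and a rooted
variant compares non-root clades normalized by 2(n−2) for when the
rooting itself is part of the estimate. The unrooted implementation is
cross-checked against dendropy in the tests. The headline consistency
results use RF = 0, where the two conventions agree.

## Problem sizes used in the test suite

Oracle-equivalence and optimality checks run on randomly generated
instances (n ≤ 10 for scoring equivalence, n ≤ 7 for exhaustive
enumeration of all rooted topologies — 10,395 at n = 7); simulator
calibration uses 50,000 3-taxon genes per branch length; the end-to-end
consistency check uses the 15-taxon / 1000-gene condition above. These
sizes were chosen so the full suite exercises every guarantee at
desk scale while remaining quick to run.

## Known limitations

* Unrooted or multifurcating gene trees are rejected, not resolved or
  rerooted.
* No branch-length (coalescent-unit) estimation on the output tree.
* Constrained mode searches only gene-tree SBPs; no search-space
  augmentation is performed, so with few or atypical gene trees the
  constrained optimum can fall short of the exact optimum (the exact
  score is always an upper bound, verified in tests).
* Exact mode is exponential and practical only to ~15 taxa.
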