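# Methods

This note documents the models and procedures implemented in `multiroot`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Problem setting

The input is an unrooted binary species tree on *n* ≥ 5 species and a set
of gene family trees whose leaves are gene copies (a species may appear
zero, one or many times per tree). Two biological processes decouple gene
trees from the species tree: gene duplication and loss (GDL), which creates
multi-copy trees, and incomplete lineage sorting (ILS), modeled by the
multispecies coalescent (MSC), which perturbs topologies even for
single-copy genes. The task is to select one of the 2n−3 edges of the
species tree as the root.

## Stage 1: duplication-aware decomposition

**Tagging.** For a rooted gene family tree, each internal node is a
*duplication* iff the species sets under two of its children intersect,
else a *speciation*. This is the standard species-overlap criterion; it
requires no species tree.

**Root choice.** The unrooted gene family tree is rooted on the edge
minimizing, lexicographically, (number of duplication nodes, loss
surrogate), with ties broken by the canonical edge identifier. Losses
cannot be counted without a species tree, so the surrogate charges, at each
duplication node, the number of species found under exactly one of its two
children — a lower bound on the losses that duplication implies. The
implementation is an incremental rerooting scan (directional species sets
per directed edge; moving the root across an edge changes exactly one
node's tag), and a quadratic tag-every-rooting reference implementation is
kept in the code base; the test suite asserts their equality on a thousand
random multi-copy trees.

**Decomposition.** Duplication nodes are processed bottom-up. A binary
duplication node always sheds one child subtree: the one covering fewer
species (ties: fewer leaves, then the subtree whose smallest leaf label
sorts later is shed, so the lexicographically earliest material is kept).
Polytomous duplication nodes shed children until the remaining children's
species sets are pairwise disjoint. Every emitted tree is single-copy
(asserted at run time); leaves are conserved exactly before the size
filter. Trees with fewer than `min_size` leaves (default 4 — a tree that
cannot cover a quintet after losing one leaf is of little use downstream)
are dropped and counted.

## Stage 2: quintet rooting under the MSC

**Why quintets.** Five is the smallest taxon count for which the
distribution of *unrooted* gene-tree topologies identifies the *rooted*
species tree under the MSC. The package expresses that identifiability as,
per rooted 5-taxon topology R, an *order structure*: a set E(R) of pairs of
topology indices whose probabilities are equal for every choice of branch
lengths, and a set G(R) of ordered pairs (i, j) with p_i ≥ p_j everywhere
and p_i > p_j generically.

**The cost.** For an empirical distribution û with support m > 0,

```
cost(R, û) = Σ_{(i,j) ∈ E(R)} |û_i − û_j|  +  Σ_{(i,j) ∈ G(R)} max(0, û_j − û_i)
```

This is the minimal L1-type penalty that vanishes exactly on distributions
consistent with R. Quintets contribute equally regardless of support
(support is reported so users can filter); quintets with m = 0 are skipped,
and if every quintet is uninformative the rooting fails explicitly.

**Deriving the order structures.** Rather than transcribing constraint
sets from the theoretical literature, the package derives them from its
own Monte-Carlo MSC oracle (a vectorized 5-taxon coalescent simulator:
lineages coalesce at rate k(k−1)/2 per coalescent unit within each branch,
freely above the root; pendant branch lengths are irrelevant). For each of
the three unlabeled rooted shapes, 200 branch-length draws are taken
uniformly from [0.05, 2.0] coalescent units per internal edge (spanning
strong to weak ILS while avoiding zero-information degeneracies), with
2×10⁶ topology samples per draw. Verdicts per ordered pair, with SE the
standard error of the estimated difference:

* **equality** — |p_i − p_j| ≤ 4 SE in *every* draw;
* **ordering** — p_i − p_j > −4 SE in every draw *and* > +6 SE in at least
  one draw;
* anything else is **omitted** (recorded, never guessed).

Two numerical choices deserve justification. The 4 SE tolerance keeps the
family-wise probability of wrongly discarding a true equality across 200
draws near 1%, where a 3 SE rule would discard ~40% of them. The
weak-order rule (never reversed + strict somewhere) exists because the
orderings that distinguish rooting *within a cherry* — e.g. whether the
cherry-cd or cherry-ce topology is more frequent under a caterpillar — have
margins that vanish as ILS vanishes; demanding a strict margin in every
draw would discard exactly the relations that make the root identifiable,
and measurably collapses the two cherry-pendant rootings into a tie.

The derived structures are symmetrized over the automorphism group of each
shape's canonical labeling (a pair is kept only if all its automorphic
images were kept) and the equalities are closed transitively, so equality
is an equivalence relation and permutation covariance is exact by
construction. Structures for all 105 rooted topologies are obtained by
relabeling the three canonical ones — valid because the MSC probability
vector is equivariant under taxon permutations — and cached in a small TSV
shipped with the package; the pipeline never re-derives them.

**Quintet sampling.** Exhaustive mode scores all C(n,5) quintets; linear
mode maps each of the n−3 internal edges to one quintet (the smallest leaf
of each of the four subtrees hanging off the edge, plus the smallest unused
leaf of the largest such subtree — a deterministic quadripartition
representative); random mode draws k distinct quintets. Per informative
quintet the 7 rooting costs are computed once; scoring any rooting of the
species tree is then a restriction plus a lookup, so linear mode performs
at most 7(n−3) cost evaluations and pre-processing work linear in the
number of gene trees (asserted by operation counters in the tests).

**Known behaviors at the theory's edges.**

* *Anomaly zone.* For caterpillar quintets with very short lower internal
  branches and a long top branch, a non-matching topology overtakes the
  matching one (measured: 0.121 vs 0.078 at lengths (0.05, 0.05, 2.0)).
  The matching topology is therefore *not* asserted to be the strict
  maximum; the derived structure simply omits the affected pair.
* *No ILS, no signal.* A point-mass û (zero discordance) satisfies every
  rooted topology's constraints: all 7 rootings cost zero. This is
  correct — without ILS the root location leaves no trace in unrooted
  topologies — and it is why the method needs *enough* ILS to work.
* *Balanced-root boundary.* Distributions generated by a balanced rooted
  quintet satisfy the weak-order constraints of the two adjacent
  caterpillar rootings with equality, so those three candidates separate
  only through noise terms. The ranked table surfaces such near-ties; no
  hidden tie-break pretends otherwise. At the whole-tree level the effect
  is mild (the competing roots are one edge from the truth, and other
  quintets still discriminate), but exact root recovery is intrinsically
  harder when the true root is a balanced split of a quintet.

## Evaluation metrics

RF distance is the symmetric difference of nontrivial bipartition sets
(normalized by 2(n−3)); nCD is the symmetric difference of proper
nontrivial clade sets normalized by 2n−4, so it is exactly 1 for a
maximally wrong rooting. When the two rooted trees share an unrooted
topology, the clade difference equals twice the number of edges between
the root positions; `ncd` computes the root distance independently (BFS on
the edge graph) and asserts the relation. The expected nCD of rooting on a
uniformly random edge is computed exactly by averaging over all 2n−3
rootings and serves as the uninformed baseline.

## The synthetic-data generator

The generator emulates the standard benchmarking protocol for this problem
at desk scale; its defaults are the study conditions used by the test
suite and the acceptance script.

* **Species tree**: Yule process conditioned on n_species = 21 tips
  (birth rate 1.0), rescaled to height 1.0 time units; ultrametric.
* **Locus trees**: a birth–death walk of gene lineages down the species
  tree. Duplication and loss rates are quoted on the per-substitution
  scale common to GDL simulators and converted to the internal clock by
  `rate_scale` = 10¹¹, so the conventional "moderate" rate 10⁻¹² yields
  0.1 events per lineage per time unit — about 0.5 duplication events per
  gene on the default tree, and rate sweeps reproduce relative, not
  absolute, regimes. The loss rate defaults to the duplication rate.
  All-extinct families are skipped and counted.
* **Gene trees**: the MSC inside each locus tree, with time converted to
  coalescent units by `ils_scale` (coalescent units per time unit; small
  multiplier = short coalescent branches = high ILS). It stands in for a
  haploid effective population size. Presets calibrated once on the
  default configuration: `ILS_LOW_SCALE` = 20.0 (AD ≈ 0.20) and
  `ILS_HIGH_SCALE` = 2.4 (AD ≈ 0.64), where AD is the mean normalized RF
  between locus and gene trees; per-replicate AD varies with the drawn
  species tree (roughly ±0.1).
* **Estimation-error proxy**: sequence simulation and maximum-likelihood
  gene-tree estimation are replaced by random NNI moves per gene tree;
  `GTEE_MODERATE_OPS` = 11 is calibrated to a mean normalized RF of ≈0.40
  on 21-taxon trees.

Simplifications relative to full GDL+ILS simulators: coalescence runs
independently within the locus tree (no bounded-coalescence hemiplasy
between duplicate copies); no sequence evolution, so estimation error is
purely topological noise rather than the structured, branch-length-
dependent error of a likelihood pipeline; no rate heterogeneity (it would
affect only sequences, which are not simulated). Passing tests therefore
demonstrate correctness of the pipeline under the stated generative model
and its calibrated discordance levels, not performance on empirical gene
trees estimated from sequences.

## Problem sizes used by the tests and the acceptance script

Metric identities are exact and tested on 1000 random rerooting pairs
(n ∈ 5..30). Decomposition guarantees are tested on 1000 random multi-copy
trees, with the incremental rooting scan checked against the quadratic
reference on 1000 instances of up to 8 leaves. The coalescent oracle is
validated against the uniform law at zero branch lengths (10⁶ samples) and
the (2/3)e^(−t) quartet law (2×10⁴ genes at t = 0.5). Five-taxon
consistency uses 20 replicates of 10⁴ gene trees on a caterpillar with
0.5-coalescent-unit internal branches. The end-to-end experiment uses 10
replicates of 21 species with 1000 simulated gene families each (moderate
duplication 10⁻¹², high-ILS calibration, linear sampling), comparing mean
nCD at 1000 and at 100 genes against the exact random-edge baseline. These
sizes keep the full suite within a few minutes on one CPU while leaving
every statistical check at least 3 standard errors of headroom.

## Limitations

* The order structures are empirical: pairs whose verdicts are unstable
  are omitted, which weakens discrimination slightly rather than biasing
  it; omission counts are recorded in the cached table's provenance.
* The weak-order rule can in principle admit a pair whose true relation
  reverses by less than the detection threshold somewhere in the draw
  range; the cost impact of such a pair is bounded by that same margin.
* The decomposition's loss surrogate is a tie-breaker, not a true loss
  count; rootings that differ only in implied losses may be ordered
  differently than by a reconciliation-based count.
* Rooting accuracy degrades, by design of the signal source, when ILS is
  very low (little signal) or gene-tree error is very high (signal
  swamped); the simulator's calibration knobs let users map that envelope
  for their own regimes.
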