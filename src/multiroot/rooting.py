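"""Quintet-based rooting of an unrooted species tree, and the full pipeline.

Given single-copy gene trees that disagree with the species tree because of
incomplete lineage sorting, the rooting stage:

1. samples a set of quintets (5-taxon subsets) from the species tree --
   exhaustively (all C(n,5)), linearly (one quintet per internal edge), or
   at random;
2. estimates, per quintet, the empirical distribution of the 15 unrooted
   quintet topologies across the gene trees;
3. pre-computes, per informative quintet, the cost of each of the 7
   rootings of the quintet topology induced by the species tree;
4. scores each of the 2n-3 rootings of the species tree by summing, over
   quintets, the cost of the rooted quintet that rooting induces, and
   returns the minimum-score rooting together with the full ranked table.

The full pipeline (`disco_qr`) first decomposes multi-copy gene family
trees into single-copy trees, then applies the rooting stage to them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .disco import DEFAULT_MIN_SIZE, DiscoResult, disco
from .quintet import (
    OrderStructure,
    QuintetCatalog,
    QuintetDistribution,
    rooting_cost,
)
from .tree import (
    DEFAULT_MAPPING,
    SpeciesMapping,
    Tree,
    TreeValidationError,
    enumerate_rootings,
    restrict,
)

__all__ = [
    "SamplingPlan",
    "ScoreRow",
    "RootingScoreTable",
    "sample_quintets",
    "estimate_quintet_distribution",
    "score_rootings",
    "disco_qr",
]


# ---------------------------------------------------------------------------
# Quintet sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplingPlan:
    mode: str  # exhaustive | linear | random
    quintets: list[frozenset[str]]
    edge_map: dict[tuple[str, ...], frozenset[str]] | None = None  # linear only
    seed: int | None = None


def _leafsets_below(tree: Tree) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for v in tree.postorder():
        if v.is_leaf:
            out[id(v)] = frozenset((v.label,))
        else:
            out[id(v)] = frozenset().union(*(out[id(c)] for c in v.children))
    return out


def sample_quintets(
    species_tree: Tree, mode: str = "exhaustive", k: int | None = None,
    seed: int | None = None,
) -> SamplingPlan:
    """Choose the quintets whose topology distributions will drive rooting.

    ``exhaustive`` enumerates all C(n,5) subsets; ``linear`` maps each of
    the n-3 internal edges to one quintet (the smallest leaf of each of the
    four subtrees hanging off the edge, plus the smallest unused leaf of the
    largest of those subtrees); ``random`` draws ``k`` distinct subsets.
    """
    if species_tree.rooted:
        raise TreeValidationError("sample_quintets expects an unrooted species tree")
    labels = sorted(species_tree.leaf_labels())
    n = len(labels)
    if n < 5:
        raise TreeValidationError("rooting requires at least five taxa")

    if mode == "exhaustive":
        quintets = [frozenset(c) for c in itertools.combinations(labels, 5)]
        return SamplingPlan("exhaustive", quintets)

    if mode == "linear":
        if not species_tree.is_binary():
            raise TreeValidationError("linear sampling requires a binary tree")
        below = _leafsets_below(species_tree)
        full = frozenset(labels)
        from .tree import edge_id_of_side

        edge_map: dict[tuple[str, ...], frozenset[str]] = {}
        quintets: list[frozenset[str]] = []
        top = species_tree.root
        for v in species_tree.postorder():
            if v.is_leaf or v is top:
                continue
            u = v.parent
            # internal edge: both endpoints internal
            # four components hanging off edge (u, v)
            comps = [below[id(c)] for c in v.children]
            comps += [below[id(c)] for c in u.children if c is not v]
            if u is not top:
                comps.append(full - below[id(u)])
            if len(comps) != 4:
                continue  # pendant edge or non-binary locality
            chosen = {min(c) for c in comps}
            largest = max(comps, key=lambda c: (len(c), min(c)))
            extra = min(x for x in largest if x not in chosen)
            q = frozenset(chosen | {extra})
            assert len(q) == 5
            eid = edge_id_of_side(below[id(v)], full)
            edge_map[eid] = q
            quintets.append(q)
        # dedupe, preserving order
        seen: set[frozenset[str]] = set()
        uniq = []
        for q in quintets:
            if q not in seen:
                seen.add(q)
                uniq.append(q)
        return SamplingPlan("linear", uniq, edge_map=edge_map)

    if mode == "random":
        if k is None or k < 1:
            raise TreeValidationError("random sampling requires k >= 1")
        total = math.comb(n, 5)
        k = min(k, total)
        rng = np.random.default_rng(seed)
        chosen: set[frozenset[str]] = set()
        while len(chosen) < k:
            idx = rng.choice(n, size=5, replace=False)
            chosen.add(frozenset(labels[i] for i in idx))
        return SamplingPlan("random", sorted(chosen, key=sorted), seed=seed)

    raise TreeValidationError(f"unknown sampling mode {mode!r}")


# ---------------------------------------------------------------------------
# Quintet topology distributions
# ---------------------------------------------------------------------------

def estimate_quintet_distribution(
    gene_trees: list[Tree], quintet, catalog: QuintetCatalog | None = None,
    counters: dict | None = None,
) -> QuintetDistribution:
    """Empirical topology frequencies of one quintet across the gene trees.

    Gene trees must be single-copy with species-name leaves. Trees missing
    any of the five species, or whose restriction is unresolved, do not
    count toward the support.
    """
    q = frozenset(quintet)
    if catalog is None:
        catalog = QuintetCatalog(q)
    counts = np.zeros(15, dtype=np.int64)
    m = 0
    for gt in gene_trees:
        if not q <= gt.leaf_labels():
            continue
        sub = restrict(gt, q)
        if counters is not None:
            counters["n_restrictions_preprocess"] += 1
        idx = catalog.topology_index(sub)
        if idx is None:
            continue  # unresolved quintet (polytomy in the gene tree)
        counts[idx] += 1
        m += 1
    freqs = counts / m if m > 0 else counts.astype(float)
    return QuintetDistribution(freqs=freqs, support=m)


# ---------------------------------------------------------------------------
# Scoring all rootings
# ---------------------------------------------------------------------------

@dataclass
class ScoreRow:
    edge_id: tuple[str, ...]
    score: float
    rank: int
    n_informative_quintets: int


@dataclass
class RootingScoreTable:
    rows: list[ScoreRow]
    species_tree: Tree  # the unrooted input
    rooted_tree: Tree  # the rank-1 rooting
    best_edge: tuple[str, ...]
    ties: list[tuple[str, ...]]  # edges tied with the best score
    n_informative_quintets: int
    counters: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)


_TIE_EPS = 1e-12


def score_rootings(
    species_tree: Tree,
    gene_trees: list[Tree],
    plan: SamplingPlan | None = None,
    structures: dict[str, OrderStructure] | None = None,
) -> RootingScoreTable:
    """Score all 2n-3 rootings of the species tree against the gene trees.

    Per informative quintet the 7 rooting costs are computed once; scoring a
    candidate rooting then only requires looking up which rooted quintet it
    induces. Uninformative quintets (no gene tree covers all five species
    with a resolved topology) are skipped; if every quintet is
    uninformative, rooting fails explicitly rather than returning an
    arbitrary root.
    """
    if species_tree.rooted:
        raise TreeValidationError("score_rootings expects an unrooted species tree")
    if not species_tree.is_binary():
        raise TreeValidationError("species tree must be binary")
    if species_tree.n_leaves < 5:
        raise TreeValidationError("rooting requires at least five taxa")
    if plan is None:
        plan = sample_quintets(species_tree, "exhaustive")

    counters = {
        "n_rooting_cost_evals": 0,
        "n_restrictions_preprocess": 0,
        "n_restrictions_scoring": 0,
    }

    # pre-processing: per informative quintet, cost of each of the 7 rootings
    per_quintet: list[tuple[frozenset[str], QuintetCatalog, dict]] = []
    for q in plan.quintets:
        catalog = QuintetCatalog(q, structures=structures)
        dist = estimate_quintet_distribution(
            gene_trees, q, catalog, counters=counters
        )
        if not dist.informative:
            continue
        ti = catalog.topology_index(restrict(species_tree, q))
        costs: dict = {}
        for rid in catalog.rootings[ti]:
            costs[rid] = rooting_cost(catalog.structure_of(rid), dist)
            counters["n_rooting_cost_evals"] += 1
        per_quintet.append((q, catalog, costs))

    if not per_quintet:
        raise TreeValidationError(
            "no informative quintet: every sampled quintet lacks gene-tree support"
        )

    rows: list[ScoreRow] = []
    rooted_by_edge: dict[tuple[str, ...], Tree] = {}
    for eid, rooted in enumerate_rootings(species_tree):
        score = 0.0
        for q, catalog, costs in per_quintet:
            sub = restrict(rooted, q)
            counters["n_restrictions_scoring"] += 1
            score += costs[catalog.rooted_id(sub)]
        rows.append(ScoreRow(eid, score, rank=0, n_informative_quintets=len(per_quintet)))
        rooted_by_edge[eid] = rooted

    rows.sort(key=lambda r: (r.score, r.edge_id))
    for i, r in enumerate(rows):
        r.rank = i + 1
    best = rows[0]
    ties = [r.edge_id for r in rows if abs(r.score - best.score) <= _TIE_EPS]
    return RootingScoreTable(
        rows=rows,
        species_tree=species_tree,
        rooted_tree=rooted_by_edge[best.edge_id],
        best_edge=best.edge_id,
        ties=ties,
        n_informative_quintets=len(per_quintet),
        counters=counters,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def disco_qr(
    gene_family_trees: list[Tree],
    species_tree: Tree,
    mapping: SpeciesMapping = DEFAULT_MAPPING,
    min_size: int = DEFAULT_MIN_SIZE,
    mode: str = "linear",
    k: int | None = None,
    seed: int | None = None,
    structures: dict[str, OrderStructure] | None = None,
) -> RootingScoreTable:
    """Root a species tree from multi-copy gene family trees.

    Pipeline: decompose each gene family tree into single-copy trees, then
    score every rooting of the species tree against them. The returned
    table's ``log`` records stage counts (input trees, single-copy trees,
    quintets used, informative quintets, pruned trees).
    """
    if not gene_family_trees:
        raise TreeValidationError("decomposition stage: empty gene tree input")
    if species_tree.rooted:
        raise TreeValidationError("species tree input must be unrooted")
    species = frozenset(species_tree.leaf_labels())

    dres: DiscoResult = disco(gene_family_trees, mapping, min_size=min_size)
    single_copy: list[Tree] = []
    n_pruned = 0
    for t in dres.trees:
        extra = t.leaf_labels() - species
        if extra:
            keep = t.leaf_labels() & species
            n_pruned += 1
            if len(keep) < min_size:
                continue
            t = restrict(t, keep)
        single_copy.append(t)
    if not single_copy:
        raise TreeValidationError(
            "decomposition stage produced no usable single-copy trees"
        )

    plan = sample_quintets(species_tree, mode=mode, k=k, seed=seed)
    try:
        table = score_rootings(species_tree, single_copy, plan, structures=structures)
    except TreeValidationError as exc:
        raise TreeValidationError(f"rooting stage: {exc}") from exc
    table.log = {
        "n_input_trees": dres.n_input_trees,
        "n_single_copy_trees": len(single_copy),
        "n_decomposition_errors": dres.n_errors,
        "n_trees_with_unknown_species": n_pruned,
        "n_quintets": len(plan.quintets),
        "n_informative_quintets": table.n_informative_quintets,
        "mode": plan.mode,
    }
    return table
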