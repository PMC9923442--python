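import math

import numpy as np
import pytest

from multiroot.metrics import unroot
from multiroot.quintet import QuintetCatalog, msc_quintet_counts, rooting_cost
from multiroot.rooting import (
    disco_qr,
    estimate_quintet_distribution,
    sample_quintets,
    score_rootings,
)
from multiroot.tree import (
    TreeValidationError,
    parse_newick,
    random_binary_tree,
    restrict,
)


def clean_gene_trees_from_counts(counts, catalog):
    """Expand a topology count vector into a list of gene trees."""
    out = []
    for idx, c in enumerate(counts):
        t = parse_newick(catalog.unrooted_newicks[idx])
        out.extend(t.copy() for _ in range(int(c)))
    return out


def caterpillar_with_lengths(value=0.5):
    t = parse_newick("((((a,b),c),d),e);")
    for v in t.postorder():
        if not v.is_leaf and v is not t.root:
            v.length = value
    return t


class TestSampleQuintets:
    def test_exhaustive_five_taxa(self):
        t = parse_newick("(a,b,(c,(d,e)));")
        plan = sample_quintets(t, "exhaustive")
        assert plan.quintets == [frozenset("abcde")]

    def test_exhaustive_count(self, rng):
        t = random_binary_tree([f"s{i:02d}" for i in range(21)], rng, rooted=False)
        plan = sample_quintets(t, "exhaustive")
        assert len(plan.quintets) == math.comb(21, 5) == 20349

    def test_linear_one_quintet_per_internal_edge(self, rng):
        t = random_binary_tree([f"s{i:02d}" for i in range(21)], rng, rooted=False)
        plan = sample_quintets(t, "linear")
        assert len(plan.edge_map) == 21 - 3
        for q in plan.quintets:
            assert len(q) == 5 and q <= t.leaf_labels()

    def test_random_mode_distinct_and_reproducible(self, rng):
        t = random_binary_tree([f"s{i:02d}" for i in range(12)], rng, rooted=False)
        p1 = sample_quintets(t, "random", k=20, seed=5)
        p2 = sample_quintets(t, "random", k=20, seed=5)
        assert p1.quintets == p2.quintets
        assert len(set(p1.quintets)) == 20

    def test_too_few_taxa(self):
        with pytest.raises(TreeValidationError, match="five"):
            sample_quintets(parse_newick("(a,b,(c,d));"), "exhaustive")


class TestEstimateDistribution:
    def test_point_mass(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        gt = parse_newick(cat.unrooted_newicks[4])
        dist = estimate_quintet_distribution([gt] * 100, frozenset("abcde"), cat)
        assert dist.support == 100
        assert dist.freqs[4] == 1.0

    def test_missing_species_flagged(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        gt = parse_newick("((a,b),(c,d));")  # e missing
        dist = estimate_quintet_distribution([gt] * 10, frozenset("abcde"), cat)
        assert dist.support == 0 and not dist.informative

    def test_unresolved_restriction_not_counted(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        gt = parse_newick("(a,b,c,d,e);", rooted_hint=False)  # star tree
        dist = estimate_quintet_distribution([gt] * 5, frozenset("abcde"), cat)
        assert dist.support == 0

    def test_low_ils_simulation_recovers_topology(self, structures):
        true = caterpillar_with_lengths(8.0)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 10_000, seed=11)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        dist = estimate_quintet_distribution(gene_trees, frozenset("abcde"), cat)
        mi = cat.matching_index(cat.rooted_id(true))
        assert dist.freqs[mi] >= 0.99


class TestScoreRootings:
    def test_five_taxon_table_equals_quintet_costs(self, structures):
        """With one quintet the table rows are exactly the 7 rooting costs."""
        true = caterpillar_with_lengths(0.5)
        S = unroot(true)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 8000, seed=13)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        table = score_rootings(S, gene_trees, structures=structures)
        assert len(table.rows) == 7
        assert sorted(r.rank for r in table.rows) == list(range(1, 8))
        dist = estimate_quintet_distribution(gene_trees, frozenset("abcde"), cat)
        ti = cat.topology_index(restrict(S, frozenset("abcde")))
        by_rid = {
            rid: rooting_cost(cat.structure_of(rid), dist)
            for rid in cat.rootings[ti]
        }
        for row in table.rows:
            # each row's score matches the induced rooted quintet's cost
            from multiroot.tree import enumerate_rootings

            rooted = dict(enumerate_rootings(S))[row.edge_id]
            assert row.score == pytest.approx(by_rid[cat.rooted_id(rooted)])

    def test_brute_force_minimum_on_five_taxa(self, structures):
        true = caterpillar_with_lengths(0.5)
        S = unroot(true)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 8000, seed=17)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        table = score_rootings(S, gene_trees, structures=structures)
        assert table.rows[0].score == min(r.score for r in table.rows)
        assert table.best_edge == table.rows[0].edge_id

    def test_gene_tree_order_invariance(self, structures):
        true = caterpillar_with_lengths(0.5)
        S = unroot(true)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 2000, seed=19)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        t1 = score_rootings(S, gene_trees, structures=structures)
        t2 = score_rootings(S, gene_trees[::-1], structures=structures)
        assert [(r.edge_id, r.score) for r in t1.rows] == [
            (r.edge_id, r.score) for r in t2.rows
        ]

    def test_irrelevant_gene_trees_change_nothing(self, structures):
        true = caterpillar_with_lengths(0.5)
        S = unroot(true)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 2000, seed=23)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        noise = [parse_newick("((a,b),(c,d));")] * 50  # e missing: no quintet
        t1 = score_rootings(S, gene_trees, structures=structures)
        t2 = score_rootings(S, gene_trees + noise, structures=structures)
        assert [r.score for r in t1.rows] == [r.score for r in t2.rows]

    def test_all_uninformative_fails_explicitly(self, structures):
        S = unroot(caterpillar_with_lengths())
        with pytest.raises(TreeValidationError, match="informative"):
            score_rootings(S, [parse_newick("((a,b),(c,d));")], structures=structures)

    def test_linear_mode_cost_evaluation_budget(self, structures, rng):
        """Linear sampling: at most 7(n-3) rooting-cost evaluations."""
        from multiroot.simulate import SimConfig, simulate_replicate

        rep = simulate_replicate(SimConfig(n_genes=50, dup_rate=0, seed=42))
        S = unroot(rep.species_tree)
        n = S.n_leaves
        plan = sample_quintets(S, "linear")
        gene_trees = [t.relabeled(lambda l: l.split("_")[0]) for t in rep.gene_trees]
        table = score_rootings(S, gene_trees, plan, structures=structures)
        assert table.counters["n_rooting_cost_evals"] <= 7 * (n - 3)

    def test_exhaustive_linear_agreement_strong_signal(self, structures, rng):
        """With low ILS and many clean gene trees both sampling modes find
        the same root edge."""
        from multiroot.simulate import SimConfig, simulate_replicate

        agree = 0
        for rep_i in range(6):
            rep = simulate_replicate(
                SimConfig(
                    n_species=8, n_genes=400, dup_rate=0, ils_scale=8.0,
                    seed=900 + rep_i,
                )
            )
            S = unroot(rep.species_tree)
            gts = [t.relabeled(lambda l: l.split("_")[0]) for t in rep.gene_trees]
            te = score_rootings(
                S, gts, sample_quintets(S, "exhaustive"), structures=structures
            )
            tl = score_rootings(
                S, gts, sample_quintets(S, "linear"), structures=structures
            )
            agree += te.best_edge == tl.best_edge
        assert agree >= 5


class TestDiscoQR:
    def test_single_copy_inputs_match_direct_qr(self, structures):
        true = caterpillar_with_lengths(0.5)
        S = unroot(true)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 3000, seed=29)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        direct = score_rootings(S, gene_trees, structures=structures)
        piped = disco_qr(gene_trees, S, mode="exhaustive", structures=structures)
        assert piped.best_edge == direct.best_edge
        assert [r.score for r in piped.rows] == pytest.approx(
            [r.score for r in direct.rows]
        )

    def test_empty_input_is_stage_one_error(self):
        S = unroot(caterpillar_with_lengths())
        with pytest.raises(TreeValidationError):
            disco_qr([], S)

    def test_unknown_species_pruned_with_log(self, structures):
        true = caterpillar_with_lengths(0.5)
        S = unroot(true)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        counts = msc_quintet_counts(true, 2000, seed=31)
        gene_trees = clean_gene_trees_from_counts(counts, cat)
        # graft an extra species onto some gene trees
        extra = [parse_newick("(((a,b),(c,z)),(d,e));") for _ in range(5)]
        table = disco_qr(
            gene_trees + extra, S, mode="exhaustive", min_size=4,
            structures=structures,
        )
        assert table.log["n_trees_with_unknown_species"] == 5

    def test_end_to_end_with_duplications(self, structures):
        """Moderate duplication, high ILS: the pipeline runs and the chosen
        root beats the random baseline on average."""
        from multiroot.metrics import evaluate_rooting, expected_random_rooting_ncd
        from multiroot.simulate import SimConfig, simulate_replicate

        ncds, bases = [], []
        for seed in (7, 8):
            rep = simulate_replicate(SimConfig(n_genes=200, seed=seed))
            S = unroot(rep.species_tree)
            table = disco_qr(rep.gene_trees, S, mode="linear", structures=structures)
            report, _curve = evaluate_rooting(table, rep.species_tree)
            ncds.append(report.ncd)
            bases.append(expected_random_rooting_ncd(rep.species_tree))
            assert table.log["n_single_copy_trees"] >= 200
        assert np.mean(ncds) < np.mean(bases)
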