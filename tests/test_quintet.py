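import itertools

import numpy as np
import pytest

from multiroot.quintet import (
    SHAPES,
    OrderStructure,
    QuintetCatalog,
    QuintetDistribution,
    classify_shape,
    derive_order_structure,
    load_structures,
    msc_quintet_counts,
    msc_quintet_probs,
    rooting_cost,
    write_structures,
)
from multiroot.tree import TreeValidationError, enumerate_rootings, parse_newick


def with_lengths(newick: str, value: float):
    t = parse_newick(newick)
    for v in t.postorder():
        if not v.is_leaf and v is not t.root:
            v.length = value
    return t


class TestCatalog:
    def test_counts(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        assert len(cat.unrooted_newicks) == 15
        assert all(len(r) == 7 for r in cat.rootings)
        assert len({rid for r in cat.rootings for rid in r}) == 105

    def test_index_maps_are_inverse(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        for i, nwk in enumerate(cat.unrooted_newicks):
            assert cat.topology_index(parse_newick(nwk)) == i

    def test_wrong_label_count(self, structures):
        with pytest.raises(TreeValidationError):
            QuintetCatalog(list("abcd"), structures=structures)

    def test_shape_census(self, structures):
        """105 rooted quintets: 60 caterpillars, 30 balanced, 15 pseudo."""
        cat = QuintetCatalog(list("abcde"), structures=structures)
        census: dict[str, int] = {}
        for rids in cat.rootings:
            for rid in rids:
                census[cat.shape_of(rid)] = census.get(cat.shape_of(rid), 0) + 1
        assert census == {"caterpillar": 60, "balanced": 30, "pseudo_caterpillar": 15}


class TestClassifyShape:
    @pytest.mark.parametrize(
        "newick,shape",
        [
            ("((((a,b),c),d),e);", "caterpillar"),
            ("(((a,b),c),(d,e));", "balanced"),
            ("(((a,b),(c,d)),e);", "pseudo_caterpillar"),
            ("(e,(d,(c,(b,a))));", "caterpillar"),
            ("((e,d),((a,b),c));", "balanced"),
        ],
    )
    def test_examples(self, newick, shape):
        assert classify_shape(parse_newick(newick)) == shape

    def test_rejects_wrong_size(self):
        with pytest.raises(TreeValidationError):
            classify_shape(parse_newick("((a,b),(c,d));"))


class TestMscOracle:
    def test_uniform_at_zero_lengths(self):
        t = with_lengths("((((a,b),c),d),e);", 0.0)
        p = msc_quintet_probs(t, 200_000, seed=1)
        se = np.sqrt((1 / 15) * (14 / 15) / 200_000)
        assert np.all(np.abs(p - 1 / 15) < 4 * se)

    def test_no_ils_limit(self):
        t = with_lengths("((((a,b),c),d),e);", 20.0)
        p = msc_quintet_probs(t, 50_000, seed=2)
        assert p.max() >= 0.999

    def test_deterministic_given_seed(self):
        t = with_lengths("(((a,b),c),(d,e));", 0.7)
        p1 = msc_quintet_probs(t, 50_000, seed=3)
        p2 = msc_quintet_probs(t, 50_000, seed=3)
        assert np.array_equal(p1, p2)

    def test_label_permutation_equivariance(self, structures):
        """Relabeling taxa permutes the probability vector accordingly."""
        base = with_lengths("((((a,b),c),d),e);", 0.4)
        perm = {"a": "d", "b": "e", "c": "c", "d": "a", "e": "b"}
        relabeled = base.relabeled(lambda l: perm[l])
        p1 = msc_quintet_probs(base, 400_000, seed=4)
        p2 = msc_quintet_probs(relabeled, 400_000, seed=5)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        # map each topology index through the permutation and compare
        for i, nwk in enumerate(cat.unrooted_newicks):
            t = parse_newick(nwk).relabeled(lambda l: perm[l])
            j = cat.topology_index(t)
            assert abs(p1[i] - p2[j]) < 4 * np.sqrt(0.25 / 400_000)

    def test_quartet_law_via_general_simulator(self):
        """Mismatching-quartet probability follows (2/3)exp(-t)."""
        from multiroot.metrics import normalized_rf, unroot
        from multiroot.simulate import simulate_gene_tree
        from multiroot.tree import Tree

        t = 0.5
        # rooted quartet caterpillar: only the branch above the (a,b) cherry
        # controls discordance
        locus = parse_newick(f"(((a:1,b:1):{t},c:2):1,d:3);")
        n = 6000
        mismatch = 0
        rng = np.random.default_rng(99)
        for _ in range(n):
            gt = simulate_gene_tree(locus, 1.0, rng=rng)
            mismatch += normalized_rf(unroot(gt), unroot(locus)) > 0
        expected = (2 / 3) * np.exp(-t)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(mismatch / n - expected) < 3.5 * se


class TestOrderStructures:
    def test_structure_invariants(self, structures):
        for shape in SHAPES:
            s = structures[shape]
            # equality is an equivalence relation (transitively closed)
            eq = set(s.eq_pairs)
            for (i, j), (k, l) in itertools.product(eq, eq):
                if j == k:
                    assert tuple(sorted((i, l))) in eq or i == l
            # orderings are irreflexive and consistent with equalities
            for i, j in s.gt_pairs:
                assert i != j
                assert tuple(sorted((i, j))) not in eq

    def test_structures_differ_between_shapes(self, structures):
        sigs = {
            shape: (structures[shape].eq_pairs, structures[shape].gt_pairs)
            for shape in SHAPES
        }
        assert len(set(sigs.values())) >= 2

    def test_matching_topology_dominates_for_caterpillar(self, structures):
        """The matching topology is never ordered below any other topology
        and is strictly above almost all of them. (It is not above *every*
        other topology: short lower branches with a long top branch put
        caterpillars in an anomaly zone where one non-matching topology can
        overtake the matching one.)"""
        cat = QuintetCatalog(list("abcde"), structures=structures)
        t = parse_newick("((((a,b),c),d),e);")
        rid = cat.rooted_id(t)
        mi = cat.matching_index(rid)
        s = cat.structure_of(rid)
        above = {j for i, j in s.gt_pairs if i == mi}
        below = {i for i, j in s.gt_pairs if j == mi}
        assert not below
        assert len(above) >= 12
        assert not any(mi in p for p in s.eq_pairs)

    def test_permutation_covariance_against_fresh_derivation(self, structures):
        """A fresh derivation for a relabeled caterpillar is consistent with
        permuting the canonical structure."""
        t = parse_newick("((((d,b),e),a),c);")
        fresh = derive_order_structure(t, n_draws=12, n_samples=150_000, seed=8)
        cat = QuintetCatalog(list("abcde"), structures=structures)
        canonical = cat.structure_of(cat.rooted_id(t))
        # high-precision equalities must be accepted by the fresh (noisier) run
        assert canonical.eq_pairs <= fresh.eq_pairs
        # fresh orderings must never contradict the canonical structure
        for i, j in fresh.gt_pairs:
            assert (j, i) not in canonical.gt_pairs
            assert tuple(sorted((i, j))) not in canonical.eq_pairs

    def test_round_trip_persistence(self, structures, tmp_path):
        p = tmp_path / "structures.tsv"
        write_structures(p, structures, meta="test")
        again = load_structures(p)
        for shape in SHAPES:
            assert again[shape].eq_pairs == structures[shape].eq_pairs
            assert again[shape].gt_pairs == structures[shape].gt_pairs


class TestRootingCost:
    def test_uniform_distribution_costs_zero_everywhere(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        u = QuintetDistribution(np.full(15, 1 / 15), support=100)
        for rids in cat.rootings:
            for rid in rids:
                assert rooting_cost(cat.structure_of(rid), u) == pytest.approx(0.0)

    def test_true_rooting_near_zero_cost(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        t = with_lengths("((((a,b),c),d),e);", 0.5)
        p = msc_quintet_probs(t, 500_000, seed=10)
        dist = QuintetDistribution(p, 500_000)
        rid = cat.rooted_id(t)
        assert rooting_cost(cat.structure_of(rid), dist) < 0.02

    def test_point_mass_costs_zero_for_all_rootings(self, structures):
        """A point mass means zero discordance, and without ILS the root
        position carries no signal: every rooting of the matching topology
        is cost-free, none is preferred."""
        cat = QuintetCatalog(list("abcde"), structures=structures)
        t = parse_newick("((((a,b),c),d),e);")
        rid = cat.rooted_id(t)
        mi = cat.matching_index(rid)
        point = np.zeros(15)
        point[mi] = 1.0
        dist = QuintetDistribution(point, support=100)
        for r in cat.rootings[mi]:
            assert rooting_cost(cat.structure_of(r), dist) == pytest.approx(0.0)

    def test_moderate_ils_probabilities_separate_rootings(self, structures):
        """At moderate ILS the true rooted quintet costs ~0 while distant
        rootings pay a large penalty."""
        cat = QuintetCatalog(list("abcde"), structures=structures)
        t = with_lengths("((((a,b),c),d),e);", 0.5)
        p = msc_quintet_probs(t, 500_000, seed=21)
        dist = QuintetDistribution(p, 500_000)
        rid = cat.rooted_id(t)
        mi = cat.matching_index(rid)
        costs = {r: rooting_cost(cat.structure_of(r), dist) for r in cat.rootings[mi]}
        true_cost = costs.pop(rid)
        assert true_cost < 0.02
        assert min(costs.values()) >= true_cost - 1e-9
        assert max(costs.values()) > 0.5

    def test_uninformative_distribution_rejected(self, structures):
        cat = QuintetCatalog(list("abcde"), structures=structures)
        empty = QuintetDistribution(np.zeros(15), support=0)
        rid = cat.rooted_id(parse_newick("((((a,b),c),d),e);"))
        with pytest.raises(ValueError):
            rooting_cost(cat.structure_of(rid), empty)
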