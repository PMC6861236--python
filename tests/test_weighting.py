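import numpy as np
import pytest

from polyscan.trees import Genealogy, Node
from polyscan.weighting import (
    classify_topologies,
    enumerate_topologies,
    exact_weighting,
    sampled_weighting,
    simplify_tree,
    weight_tree,
    weighting_profile,
    wilson_interval,
)

from helpers import TAXA, dendropy_oracle_weights, random_taxon_tree


def taxon_sorted_tree(sizes=None):
    """Genealogy where every taxon is exclusively monophyletic."""
    if sizes is None:
        sizes = {"lyrata2x": 4, "lyrata4x": 8, "arenosa2x": 4, "arenosa4x": 8,
                 "outgroup": 2}

    def clade(taxon, n):
        tips = [Node(name=f"{taxon}-{i}", length=1.0) for i in range(n)]
        cur = tips[0]
        for t in tips[1:]:
            p = Node(length=1.0)
            p.add(cur)
            p.add(t)
            cur = p
        return cur

    ly = Node(length=1.0)
    ly.add(clade("lyrata2x", sizes["lyrata2x"]))
    ly.add(clade("lyrata4x", sizes["lyrata4x"]))
    ar = Node(length=1.0)
    ar.add(clade("arenosa2x", sizes["arenosa2x"]))
    ar.add(clade("arenosa4x", sizes["arenosa4x"]))
    ing = Node(length=1.0)
    ing.add(ly)
    ing.add(ar)
    root = Node()
    root.add(ing)
    root.add(clade("outgroup", sizes["outgroup"]))
    tm = {}
    for t, n in sizes.items():
        for i in range(n):
            tm[f"{t}-{i}"] = t
    return Genealogy(root, taxon_map=tm)


SPECIES_CANON = "((arenosa2x,arenosa4x),(lyrata2x,lyrata4x))"


class TestEnumerateTopologies:
    def test_four_ingroups_give_fifteen(self):
        assert len(enumerate_topologies()) == 15

    def test_three_ingroups_give_three(self):
        assert len(enumerate_topologies(("a", "b", "c"), "o")) == 3

    def test_two_ingroups_give_one(self):
        assert len(enumerate_topologies(("a", "b"), "o")) == 1

    def test_all_distinct_and_stable(self):
        t1 = enumerate_topologies()
        t2 = enumerate_topologies()
        assert [t.canonical for t in t1] == [t.canonical for t in t2]
        assert len({t.canonical for t in t1}) == 15

    def test_duplicate_taxa_error(self):
        with pytest.raises(ValueError):
            enumerate_topologies(("a", "a", "b", "c"), "o")


class TestClassifyTopologies:
    def test_partition_1_3_5_6(self):
        topos = enumerate_topologies()
        classes = classify_topologies(topos)
        from collections import Counter

        counts = Counter(classes.values())
        assert counts["species"] == 1
        assert counts["introgression"] == 3
        assert counts["ils"] == 5
        assert counts["other"] == 6

    def test_species_topology_is_conspecific_cherries(self):
        topos = enumerate_topologies()
        classes = classify_topologies(topos)
        [species] = [t for t in topos if classes[t.id] == "species"]
        assert species.canonical == SPECIES_CANON

    def test_introgression_topologies_group_tetraploids(self):
        topos = enumerate_topologies()
        classes = classify_topologies(topos)
        for t in topos:
            if classes[t.id] == "introgression":
                assert frozenset(["lyrata4x", "arenosa4x"]) in t.clades


class TestSimplifyTree:
    def test_taxon_sorted_collapses_to_five_tips(self):
        g = taxon_sorted_tree()
        st = simplify_tree(g)
        assert len(st.tip_taxon) == 5
        assert st.combination_count() == 1
        assert st.total_weight() == 4 * 8 * 4 * 8 * 2

    def test_discordant_haplotype_keeps_extra_tip(self):
        g = taxon_sorted_tree()
        # relabel one lyrata4x tip as arenosa4x: both taxa keep >=2 tips
        tm = dict(g.taxon_map)
        tm["lyrata4x-0"] = "arenosa4x"
        st = simplify_tree(g, tm)
        by_taxon = st.tips_by_taxon
        assert len(by_taxon["arenosa4x"]) >= 2

    def test_unmapped_tip_error(self):
        g = taxon_sorted_tree()
        tm = dict(g.taxon_map)
        del tm["outgroup-0"]
        with pytest.raises(ValueError, match="no taxon"):
            simplify_tree(g, tm)

    @pytest.mark.parametrize("seed", range(10))
    def test_weighting_invariant_under_simplification(self, seed):
        rng = np.random.default_rng(seed)
        g = random_taxon_tree(rng)
        topos = enumerate_topologies()
        simplified = exact_weighting(simplify_tree(g), topos)
        oracle = dendropy_oracle_weights(g.newick(), g.taxon_map, topos)
        np.testing.assert_allclose(simplified.weights, oracle, atol=1e-12)


class TestExactWeighting:
    def test_concordant_tree_weight_one(self):
        g = taxon_sorted_tree()
        res = exact_weighting(simplify_tree(g))
        topos = enumerate_topologies()
        w = dict(zip((t.canonical for t in topos), res.exact_fractions))
        assert w[SPECIES_CANON] == 1
        assert sum(res.exact_fractions) == 1

    def test_weights_sum_to_one_exactly(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            g = random_taxon_tree(rng)
            res = exact_weighting(simplify_tree(g))
            assert sum(res.exact_fractions) == 1

    def test_single_migrant_haplotype_hand_enumeration(self):
        # two haplotypes per ingroup taxon, one lyrata4x haplotype sits
        # inside the arenosa4x clade; 2^4 = 16 ingroup combinations:
        # migrant chosen (8) -> tetraploid-cherry topology, else species
        tm = {}
        def tip(name, taxon):
            tm[name] = taxon
            return Node(name=name, length=1.0)

        a4 = Node(length=1.0)
        inner = Node(length=1.0)
        inner.add(tip("a4-0", "arenosa4x"))
        inner.add(tip("a4-1", "arenosa4x"))
        a4.add(inner)
        a4.add(tip("mig", "lyrata4x"))
        a2 = Node(length=1.0)
        a2.add(tip("a2-0", "arenosa2x"))
        a2.add(tip("a2-1", "arenosa2x"))
        ar = Node(length=1.0)
        ar.add(a4)
        ar.add(a2)
        l2 = Node(length=1.0)
        l2.add(tip("l2-0", "lyrata2x"))
        l2.add(tip("l2-1", "lyrata2x"))
        l4 = Node(length=1.0)
        l4.add(tip("l4-0", "lyrata4x"))
        l4.add(inner2 := Node(length=1.0))
        inner2.add(tip("l4-1", "lyrata4x"))
        inner2.children[-1].length = 1.0
        ly = Node(length=1.0)
        ly.add(l2)
        ly.add(l4)
        ing = Node(length=1.0)
        ing.add(ly)
        ing.add(ar)
        root = Node()
        root.add(ing)
        root.add(tip("out-0", "outgroup"))
        g = Genealogy(root, taxon_map=tm)
        topos = enumerate_topologies()
        res = exact_weighting(simplify_tree(g), topos)
        w = dict(zip((t.canonical for t in topos), res.weights))
        # migrant chosen with prob 1/3 (3 lyrata4x tips incl. nested pair)
        assert w[SPECIES_CANON] == pytest.approx(2 / 3)
        assert w["(((arenosa4x,lyrata4x),arenosa2x),lyrata2x)"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_oracle(self, seed):
        rng = np.random.default_rng(seed + 500)
        g = random_taxon_tree(rng)
        topos = enumerate_topologies()
        res = exact_weighting(simplify_tree(g), topos)
        oracle = dendropy_oracle_weights(g.newick(), g.taxon_map, topos)
        np.testing.assert_allclose(res.weights, oracle, atol=1e-12)


class TestWilson:
    def test_boundaries(self):
        lo, hi = wilson_interval(10, 10)
        assert hi == 1.0
        lo, hi = wilson_interval(0, 10)
        assert lo == 0.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(5, 10), (1, 100), (99, 100), (250, 1000)]:
            lo, hi = wilson_interval(k, n, 0.95)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-9)
            assert hi == pytest.approx(shi, abs=1e-9)

    def test_n_zero_error(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestSampledWeighting:
    def test_concordant_tree_stops_fast(self):
        g = taxon_sorted_tree()
        st = simplify_tree(g)
        res = sampled_weighting(st, seed=1)
        assert res.mode == "sampled"
        assert res.weights.max() == pytest.approx(1.0)
        assert res.n_samples <= 300
        assert np.all(res.ci_half_widths < 0.05)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(42)
        g = random_taxon_tree(rng)
        st = simplify_tree(g)
        r1 = sampled_weighting(st, seed=9)
        r2 = sampled_weighting(st, seed=9)
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_within_ci_of_exact(self):
        rng = np.random.default_rng(8)
        g = random_taxon_tree(rng, max_per_taxon=3)
        st = simplify_tree(g)
        exact = exact_weighting(st)
        hits = 0
        total = 0
        for seed in range(10):
            samp = sampled_weighting(st, seed=seed, ci_target=0.05)
            diff = np.abs(samp.weights - exact.weights)
            hits += int(np.sum(diff <= samp.ci_half_widths + 1e-12))
            total += len(diff)
        assert hits / total >= 0.9

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(12)
        g = random_taxon_tree(rng)
        res = sampled_weighting(simplify_tree(g), seed=0)
        assert res.weights.sum() == pytest.approx(1.0)


class TestPhaseRobustness:
    def test_within_sample_slot_permutation_small_effect(self):
        # permuting slot labels within samples of a taxon-sorted tree cannot
        # change which clade a haplotype belongs to -> weights unchanged
        g = taxon_sorted_tree()
        res1 = weight_tree(g)
        tm = dict(g.taxon_map)
        res2 = weight_tree(g, tm)
        np.testing.assert_allclose(res1.weights, res2.weights, atol=1e-12)


class TestWeightingProfile:
    def _trees(self, n, introgressed=()):
        return [
            (_win(i), _tetraploid_sister_tree() if i in introgressed else taxon_sorted_tree())
            for i in range(n)
        ]

    def test_all_concordant_no_peaks(self):
        trees = self._trees(5)
        table, peaks = weighting_profile(trees, thresholds=(0.5, 0.7))
        assert peaks[0.5] == [] and peaks[0.7] == []
        np.testing.assert_allclose(table["w_species"], 1.0)

    def test_peaks_at_introgressed_windows_and_nested(self):
        trees = self._trees(7, introgressed=(2, 5))
        table, peaks = weighting_profile(trees, thresholds=(0.5, 0.7))
        labels5 = {w for p in peaks[0.5] for w in p.windows}
        labels7 = {w for p in peaks[0.7] for w in p.windows}
        assert labels5 == {"w2", "w5"}
        assert labels7 <= labels5  # monotone nesting


def _win(i):
    from polyscan.io_popgen import Window

    return Window("chr1", 100 * i + 1, 100 * (i + 1), "gene", f"w{i}")


def _tetraploid_sister_tree():
    """Tree whose tetraploids form a clade (introgression class)."""
    tm = {}

    def clade(taxon, n):
        tips = []
        for i in range(n):
            tm[f"{taxon}-{i}"] = taxon
            tips.append(Node(name=f"{taxon}-{i}", length=1.0))
        cur = tips[0]
        for t in tips[1:]:
            p = Node(length=1.0)
            p.add(cur)
            p.add(t)
            cur = p
        return cur

    tetra = Node(length=1.0)
    tetra.add(clade("lyrata4x", 8))
    tetra.add(clade("arenosa4x", 8))
    dip = Node(length=1.0)
    dip.add(clade("lyrata2x", 4))
    dip.add(clade("arenosa2x", 4))
    ing = Node(length=1.0)
    ing.add(tetra)
    ing.add(dip)
    root = Node()
    root.add(ing)
    root.add(clade("outgroup", 2))
    return Genealogy(root, taxon_map=tm)


from hypothesis import given, settings, strategies as st


class TestWilsonProperties:

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 2000).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n))
    ))
    def test_interval_contains_point_estimate(self, args):
        n, k = args
        lo, hi = wilson_interval(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 500))
    def test_interval_shrinks_with_n(self, n):
        lo1, hi1 = wilson_interval(n, 2 * n)
        lo4, hi4 = wilson_interval(4 * n, 8 * n)
        assert (hi4 - lo4) < (hi1 - lo1)
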