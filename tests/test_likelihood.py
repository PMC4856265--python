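"""The MSNC gene-tree-topology mass function and multi-locus likelihood."""

import math
from collections import Counter

import pytest

from oracles import _SpeciesTree, gcoal_expm, msc_gene_topology_prob

from msnc.likelihood import (GeneTreeData, GeneTreeTopology, InheritanceMap,
                             coalescence_prob, data_loglikelihood,
                             enumerate_topologies, gene_tree_mass,
                             locus_likelihood)
from msnc.network import parse_network


class TestCoalescenceProb:
    def test_single_lineage(self):
        for t in (0.0, 0.3, 5.0, math.inf):
            assert coalescence_prob(1, 1, t) == 1.0

    def test_pair_closed_form(self):
        for t in (0.1, 0.7, 3.0):
            assert coalescence_prob(2, 1, t) == \
                pytest.approx(1.0 - math.exp(-t), abs=1e-12)
            assert coalescence_prob(2, 2, t) == \
                pytest.approx(math.exp(-t), abs=1e-12)

    @pytest.mark.parametrize("u", range(2, 7))
    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_normalization(self, u, t):
        assert sum(coalescence_prob(u, v, t)
                   for v in range(1, u + 1)) == pytest.approx(1.0,
                                                              abs=1e-10)

    def test_against_matrix_exponential(self):
        for u in range(1, 9):
            for v in range(1, u + 1):
                for t in (0.05, 0.5, 2.0):
                    assert coalescence_prob(u, v, t) == \
                        pytest.approx(gcoal_expm(u, v, t), abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            coalescence_prob(2, 3, 1.0)
        with pytest.raises(ValueError):
            coalescence_prob(2, 0, 1.0)
        with pytest.raises(ValueError):
            coalescence_prob(2, 1, -1.0)


class TestGeneTreeMass:
    def test_three_taxon_closed_form(self):
        for t in (0.2, 1.0, 2.5):
            net = parse_network(f"((A:1,B:1):{t},C:2);")
            match = GeneTreeTopology.from_nested((("A", "B"), "C"))
            disc1 = GeneTreeTopology.from_nested((("A", "C"), "B"))
            disc2 = GeneTreeTopology.from_nested((("B", "C"), "A"))
            assert gene_tree_mass(net, match) == \
                pytest.approx(1 - 2 / 3 * math.exp(-t), abs=1e-12)
            for d in (disc1, disc2):
                assert gene_tree_mass(net, d) == \
                    pytest.approx(math.exp(-t) / 3, abs=1e-12)

    def test_normalization_on_networks(self, net3_1ret, net4_1ret):
        for net, labels in [(net3_1ret, "ABC"), (net4_1ret, "ABCD")]:
            total = sum(gene_tree_mass(net, g)
                        for g in enumerate_topologies(labels))
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_tree_reduction_matches_history_enumeration(self):
        # independent Degnan-Salter style oracle on a non-trivial tree
        net = parse_network("(((A:0.3,B:0.9):0.4,C:1.1):0.7,D:0.2);")
        st = _SpeciesTree(((("A", "B"), "C"), "D"),
                          {frozenset("AB"): 0.4, frozenset("ABC"): 0.7,
                           frozenset("A"): 0.3, frozenset("B"): 0.9,
                           frozenset("C"): 1.1, frozenset("D"): 0.2})
        for g in enumerate_topologies("ABCD"):
            assert gene_tree_mass(net, g) == \
                pytest.approx(msc_gene_topology_prob(st, g.nested()),
                              abs=1e-12)

    def test_gamma_boundary_reduces_to_displayed_tree(self):
        net = parse_network(
            "((A:1,(B:0.5)#H1:0.5::1.0):1,(#H1:0.5::0.0,C:1):1);")
        # gamma = 1 keeps B on the A side: displayed tree ((A,B),C) with
        # B's path 0.5 + 0.5 through the suppressed node
        displayed = parse_network("((A:1,B:1.0):1,C:2);")
        for g in enumerate_topologies("ABC"):
            assert gene_tree_mass(net, g) == \
                pytest.approx(gene_tree_mass(displayed, g), abs=1e-12)

    def test_long_branch_gamma_mixture(self):
        net = parse_network(
            "((A:20,(B:20)#H1:20::0.3):20,(#H1:20::0.7,C:20):20);")
        g_ab = GeneTreeTopology.from_nested((("A", "B"), "C"))
        g_bc = GeneTreeTopology.from_nested((("B", "C"), "A"))
        assert gene_tree_mass(net, g_ab) == pytest.approx(0.3, abs=1e-4)
        assert gene_tree_mass(net, g_bc) == pytest.approx(0.7, abs=1e-4)

    def test_single_sample_is_certain(self, net4_1ret):
        g = GeneTreeTopology(["A"], {})
        assert gene_tree_mass(net4_1ret, g) == 1.0

    def test_multiple_individuals_monophyly(self):
        net = parse_network("(A:0.7,B:1.0);")
        tmap = {"a1": "A", "a2": "A", "b1": "B"}
        mono = GeneTreeTopology.from_nested((("a1", "a2"), "b1"))
        assert gene_tree_mass(net, mono, tmap) == \
            pytest.approx(1 - 2 / 3 * math.exp(-0.7), abs=1e-12)
        total = sum(gene_tree_mass(net, g, tmap)
                    for g in enumerate_topologies(["a1", "a2", "b1"]))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_unmapped_leaf_is_error(self, tree3):
        g = GeneTreeTopology.from_nested((("A", "B"), "Z"))
        with pytest.raises(ValueError, match="Z"):
            gene_tree_mass(tree3, g)

    def test_invalid_gamma_is_error(self, net3_1ret):
        g = GeneTreeTopology.from_nested((("A", "B"), "C"))
        bad = InheritanceMap({net3_1ret.reticulation_nodes()[0]: 1.5})
        with pytest.raises(ValueError):
            gene_tree_mass(net3_1ret, g, inheritance=bad)

    def test_inheritance_override(self, net3_1ret):
        g = GeneTreeTopology.from_nested((("A", "B"), "C"))
        node = net3_1ret.reticulation_nodes()[0]
        base = gene_tree_mass(net3_1ret, g)
        overridden = gene_tree_mass(
            net3_1ret, g, inheritance=InheritanceMap({node: 0.99}))
        assert overridden != pytest.approx(base, abs=1e-6)


class TestDataLikelihood:
    def _topos(self):
        return (GeneTreeTopology.from_nested((("A", "B"), "C")),
                GeneTreeTopology.from_nested((("A", "C"), "B")))

    def test_constant_multiset_equals_single_mass(self, tree3):
        g, _ = self._topos()
        assert locus_likelihood(tree3, [g] * 100) == \
            pytest.approx(gene_tree_mass(tree3, g), abs=1e-12)

    def test_even_mixture_is_mean(self, tree3):
        g1, g2 = self._topos()
        expect = (gene_tree_mass(tree3, g1)
                  + gene_tree_mass(tree3, g2)) / 2
        assert locus_likelihood(tree3, [g1] * 50 + [g2] * 50) == \
            pytest.approx(expect, abs=1e-12)

    def test_dedup_weights_equal_full_set(self, tree3, rng):
        g1, g2 = self._topos()
        full = [g1] * 73 + [g2] * 27
        rng.shuffle(full)
        weighted = Counter({g1: 73, g2: 27})
        assert locus_likelihood(tree3, full) == \
            pytest.approx(locus_likelihood(tree3, weighted), abs=1e-15)

    def test_identical_loci_sum(self, tree3):
        g, _ = self._topos()
        data = GeneTreeData([[g]] * 7)
        assert data_loglikelihood(tree3, data) == \
            pytest.approx(7 * math.log(gene_tree_mass(tree3, g)),
                          abs=1e-10)

    def test_pooled_cache_matches_naive(self, net4_1ret, rng):
        topos = enumerate_topologies("ABCD")
        loci = [[topos[rng.integers(len(topos))] for _ in range(5)]
                for _ in range(6)]
        data = GeneTreeData(loci)
        naive = sum(math.log(locus_likelihood(net4_1ret, locus))
                    for locus in loci)
        assert data_loglikelihood(net4_1ret, data) == \
            pytest.approx(naive, abs=1e-12)

    def test_every_topology_has_positive_mass(self, net4_1ret, rng):
        # finite branch lengths always leave ILS room for any topology
        for g in enumerate_topologies("ABCD"):
            assert gene_tree_mass(net4_1ret, g) > 0.0

    def test_species_missing_from_network(self, tree3):
        g = GeneTreeTopology.from_nested((("A", "B"), "D"))
        data = GeneTreeData([[g]])
        with pytest.raises(ValueError, match="D"):
            data_loglikelihood(tree3, data)


class TestSimulatorAgreement:
    def test_frequencies_match_mass(self, net3_1ret, rng):
        from msnc.simulate import simulate_gene_tree
        n = 30_000
        counts = Counter()
        for _ in range(n):
            counts[GeneTreeTopology.from_network_tree(
                simulate_gene_tree(net3_1ret, None, rng))] += 1
        for g in enumerate_topologies("ABC"):
            p = gene_tree_mass(net3_1ret, g)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[g] / n - p) < 3.5 * se + 1e-9
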