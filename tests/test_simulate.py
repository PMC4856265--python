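"""MSNC simulator, sequence evolution, bootstrap estimation, RF distance."""

import itertools
import math
from pathlib import Path

import numpy as np
import pytest

from msnc.likelihood import GeneTreeTopology, enumerate_topologies
from msnc.network import parse_network, validate, write_network
from msnc.simulate import (GTRModel, SimConfig, estimate_gene_trees,
                           model_network_suite, rf_distance,
                           simulate_alignment, simulate_gene_tree,
                           topology_from_clades)


class TestGeneTreeSimulation:
    def test_two_species_unique_topology(self, rng):
        net = parse_network("(A:1,B:1);")
        expect = GeneTreeTopology.from_nested(("A", "B"))
        for _ in range(20):
            gt = simulate_gene_tree(net, None, rng)
            assert GeneTreeTopology.from_network_tree(gt) == expect

    def test_three_taxon_matching_frequency(self, rng):
        net = parse_network("((A:1,B:1):0.5,C:1.5);")
        n = 30_000
        match = GeneTreeTopology.from_nested((("A", "B"), "C"))
        hits = sum(
            GeneTreeTopology.from_network_tree(
                simulate_gene_tree(net, None, rng)) == match
            for _ in range(n))
        p = 1 - 2 / 3 * math.exp(-0.5)
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_gamma_one_matches_displayed_network(self, rng):
        net = parse_network(
            "((A:1,(B:0.5)#H1:0.5::1.0):1,(#H1:0.5::0.0,C:1):1);")
        displayed = parse_network("((A:1,B:1.0):1,C:2);")
        n = 20_000
        ab = GeneTreeTopology.from_nested((("A", "B"), "C"))
        f_net = sum(GeneTreeTopology.from_network_tree(
            simulate_gene_tree(net, None, rng)) == ab
            for _ in range(n)) / n
        f_dis = sum(GeneTreeTopology.from_network_tree(
            simulate_gene_tree(displayed, None, rng)) == ab
            for _ in range(n)) / n
        assert abs(f_net - f_dis) < 4 * math.sqrt(0.25 / n) * 2

    def test_leaf_conservation_with_multiple_individuals(self, rng):
        net = parse_network("((A:1,B:1):1,C:2);")
        gt = simulate_gene_tree(net, {"A": 3, "C": 2}, rng)
        assert sorted(gt.leaf_name.values()) == \
            ["A_1", "A_2", "A_3", "B", "C_1", "C_2"]

    def test_branch_lengths_nonnegative(self, rng):
        net = model_network_suite().networks[1]
        for _ in range(10):
            gt = simulate_gene_tree(net, None, rng)
            assert all(e.length >= 0 for e in gt.edges.values())
            assert validate(gt) == []


class TestSequenceSimulation:
    def test_zero_length_tree_identical_sequences(self, rng):
        gt = parse_network("((A:0,B:0):0,C:0);")
        cfg = SimConfig(loci=1, seq_length=200)
        aln = simulate_alignment(gt, cfg, rng)
        assert aln["A"] == aln["B"] == aln["C"]

    def test_jukes_cantor_saturation(self, rng):
        # theta/2 * length = 18 substitutions/site: identity -> 1/4
        gt = parse_network("(A:500,B:500);")
        cfg = SimConfig(loci=1, theta=0.072, seq_length=4000)
        aln = simulate_alignment(gt, cfg, rng)
        ident = np.mean([a == b for a, b in zip(aln["A"], aln["B"])])
        assert abs(ident - 0.25) < 4 * math.sqrt(0.25 * 0.75 / 4000)

    def test_short_branch_linearization(self, rng):
        d = 0.01  # expected substitutions per site between the leaves
        gt = parse_network(f"(A:{2 * d / 0.036:.6f},B:0);")
        cfg = SimConfig(loci=1, theta=0.036, seq_length=50_000)
        aln = simulate_alignment(gt, cfg, rng)
        diff = np.mean([a != b for a, b in zip(aln["A"], aln["B"])])
        assert diff == pytest.approx(d, rel=0.25)

    def test_invalid_gtr_rejected(self):
        with pytest.raises(ValueError):
            GTRModel(frequencies=(0.5, 0.5, 0.2, 0.2)).rate_matrix()
        with pytest.raises(ValueError):
            GTRModel(exchangeabilities=(1, 1, 1, 1, 1, -1)).rate_matrix()

    def test_gtr_rows_are_distributions(self):
        m = GTRModel(exchangeabilities=(1, 2, 1, 1, 2, 1),
                     frequencies=(0.3, 0.2, 0.2, 0.3))
        P = m.transition(0.4)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= 0).all()


class TestEstimation:
    def test_easy_signal_recovers_truth(self, rng):
        # long, well-separated branches: bootstrap NJ nearly always exact
        gt = parse_network(
            "(((A:30,B:30):30,(C:30,D:30):30):30,O:90);")
        truth = GeneTreeTopology.from_network_tree(gt)
        cfg = SimConfig(loci=1, theta=0.036, seq_length=2000,
                        bootstrap_reps=40)
        aln = simulate_alignment(gt, cfg, rng)
        (counter,) = estimate_gene_trees([aln], cfg, "O", rng,
                                         engine="nj")
        agree = counter[truth] / sum(counter.values())
        assert agree >= 0.95

    def test_missing_outgroup_is_error(self, rng):
        aln = {"A": "ACGT", "B": "ACGT"}
        with pytest.raises((ValueError, RuntimeError)):
            estimate_gene_trees([aln], SimConfig(loci=1, bootstrap_reps=2),
                                "O", rng, engine="nj")

    def test_identical_sequences_retained_not_filtered(self, rng):
        aln = {name: "ACGTACGTACGTACGTACGT" for name in "ABCO"}
        cfg = SimConfig(loci=1, bootstrap_reps=10)
        (counter,) = estimate_gene_trees([aln], cfg, "O", rng,
                                         engine="nj")
        assert sum(counter.values()) == 10  # engine output kept verbatim

    def test_unknown_engine_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_gene_trees([{"A": "AC", "O": "AC"}],
                                SimConfig(loci=1), "O", rng,
                                engine="upgma")


class TestRFDistance:
    def test_identical_trees_zero(self):
        t = GeneTreeTopology.from_nested(((("A", "B"), "C"), "D"))
        assert rf_distance(t, t) == 0.0

    def test_four_taxon_exhaustive_range(self):
        tops = enumerate_topologies("ABCD")
        vals = [rf_distance(a, b)
                for a, b in itertools.combinations(tops, 2)]
        assert max(vals) == 1.0
        assert min(vals) > 0.0  # distinct topologies never at 0
        # maximally different caterpillar pair
        a = GeneTreeTopology.from_nested(((("A", "B"), "C"), "D"))
        b = GeneTreeTopology.from_nested(((("C", "D"), "B"), "A"))
        assert rf_distance(a, b) == 1.0

    def test_symmetry(self, rng):
        tops = enumerate_topologies("ABCDE")
        for _ in range(20):
            i, j = rng.integers(len(tops), size=2)
            assert rf_distance(tops[i], tops[j]) == \
                rf_distance(tops[j], tops[i])

    def test_matches_direct_clade_computation(self, rng):
        tops = enumerate_topologies("ABCDE")
        for _ in range(20):
            a, b = (tops[rng.integers(len(tops))] for _ in range(2))
            c1 = {c for c in a.clades() if 1 < len(c) < 5}
            c2 = {c for c in b.clades() if 1 < len(c) < 5}
            expect = len(c1 ^ c2) / (len(c1) + len(c2))
            assert rf_distance(a, b) == pytest.approx(expect)

    def test_mismatched_leaf_sets_error(self):
        a = GeneTreeTopology.from_nested((("A", "B"), "C"))
        b = GeneTreeTopology.from_nested((("A", "B"), "D"))
        with pytest.raises(ValueError):
            rf_distance(a, b)


class TestModelNetworkSuite:
    def test_reticulation_counts_and_outgroup(self):
        suite = model_network_suite()
        assert [n.num_reticulations for n in suite.networks] == [1, 2, 3]
        for net in suite:
            assert validate(net) == []
            assert "O" in net.leaf_name.values()
            assert len(net.leaf_name) == 7

    def test_branch_lengths_within_stated_range(self):
        for net in model_network_suite():
            for e in net.edges.values():
                assert 0.5 <= e.length <= 1.5

    def test_matches_versioned_fixture_file(self):
        path = Path(__file__).parent.parent / "fixtures" / \
            "model_networks.enwk"
        lines = path.read_text().strip().splitlines()
        assert lines == [write_network(n) for n in model_network_suite()]


class TestTopologyFromClades:
    def test_round_trip(self):
        t = GeneTreeTopology.from_nested(((("A", "B"), "C"), ("D", "E")))
        clades = {c for c in t.clades() if 1 < len(c) < 5}
        again = topology_from_clades(t.taxa, sorted(clades, key=sorted))
        assert again == t

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            topology_from_clades(["A", "B", "C", "D"], [])


class TestParserCrossValidation:
    def test_clades_agree_with_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        taxa = [f"T{i}" for i in range(6)]
        for seed in range(5):
            tns = dendropy.TaxonNamespace(taxa)
            dtree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=6, rng=__import__("random").Random(seed))
            nwk = dtree.as_string(schema="newick",
                                  suppress_rooting=True).strip()
            ours = GeneTreeTopology.from_newick(nwk)
            theirs = {
                frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
                for nd in dtree.preorder_internal_node_iter()}
            theirs = {c for c in theirs if 1 < len(c) < 6}
            assert {c for c in ours.clades() if 1 < len(c) < 6} == theirs
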