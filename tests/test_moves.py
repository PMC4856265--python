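"""Proposal moves: selection scheme, Hastings ratios, reversibility."""

import math
from collections import Counter

import pytest

from conftest import random_network

from msnc.moves import (ADD_RETICULATION, CHANGE_INHERITANCE, CHANGE_LENGTH,
                        DELETE_RETICULATION, FLIP_RETICULATION, MOVE_HEAD,
                        MoveConfig, propose,
                        propose_add_reticulation,
                        propose_change_inheritance, propose_change_length,
                        propose_delete_reticulation,
                        propose_flip_reticulation, propose_move_head,
                        propose_move_tail, reflect_nonnegative,
                        reflect_unit, select_move, selection_probs)
from msnc.moves import _PROPOSERS
from msnc.network import canonical_topology_key, parse_network, validate

_PARTNER = {ADD_RETICULATION: DELETE_RETICULATION,
            DELETE_RETICULATION: ADD_RETICULATION}


class TestSelection:
    def test_tree_state_never_selects_reticulation_moves(self, tree3, rng):
        cfg = MoveConfig(kappa=0.5, omega=0.5, max_reticulations=3)
        probs = selection_probs(tree3, cfg)
        assert probs[DELETE_RETICULATION] == 0.0
        assert probs[CHANGE_INHERITANCE] == 0.0
        assert probs[MOVE_HEAD] == 0.0
        assert probs[FLIP_RETICULATION] == 0.0
        # the freed mass is absorbed within each group
        assert probs[ADD_RETICULATION] == pytest.approx(0.5)
        assert sum(probs.values()) == pytest.approx(1.0)
        kinds = {select_move(tree3, cfg, rng) for _ in range(300)}
        assert DELETE_RETICULATION not in kinds

    def test_dimension_moves_only_with_kappa_one(self, net3_1ret, rng):
        cfg = MoveConfig(kappa=1.0, kappa1=0.3, max_reticulations=3)
        n = 20_000
        counts = Counter(select_move(net3_1ret, cfg, rng)
                         for _ in range(n))
        assert set(counts) == {ADD_RETICULATION, DELETE_RETICULATION}
        p = counts[ADD_RETICULATION] / n
        assert abs(p - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)

    def test_kappa_zero_omega_one(self, net3_1ret, rng):
        cfg = MoveConfig(kappa=0.0, omega=1.0, max_reticulations=3)
        kinds = {select_move(net3_1ret, cfg, rng) for _ in range(500)}
        assert kinds <= {CHANGE_LENGTH, CHANGE_INHERITANCE}

    def test_probabilities_sum_to_one(self, net3_1ret):
        probs = selection_probs(net3_1ret, MoveConfig())
        assert sum(probs.values()) == pytest.approx(1.0)


class TestContinuousMoves:
    def test_change_length_symmetric_and_reflected(self, tree3, rng):
        cfg = MoveConfig()
        res = propose_change_length(
            tree3, cfg, choices={"edge": next(
                (e.tail, e.head) for e in tree3.edges.values()),
                "delta": -5.0})
        assert res.log_hastings == 0.0 and res.log_jacobian == 0.0
        assert all(e.length >= 0 for e in res.network.edges.values())
        assert canonical_topology_key(res.network) == \
            canonical_topology_key(tree3)

    def test_change_inheritance_reflection(self, net3_1ret):
        cfg = MoveConfig()
        node = net3_1ret.reticulation_nodes()[0]
        res = propose_change_inheritance(
            net3_1ret, cfg, choices={"node": node, "delta": 0.9})
        g = res.network.inheritance()[node]
        assert 0.0 <= g <= 1.0
        # 0.3 + 0.9 = 1.2 reflects at 1 to 0.8
        assert g == pytest.approx(0.8)

    def test_change_inheritance_on_tree_is_contract_violation(self, tree3,
                                                              rng):
        with pytest.raises(ValueError):
            propose_change_inheritance(tree3, MoveConfig(), rng)

    def test_reflection_helpers(self):
        assert reflect_nonnegative(-0.2) == pytest.approx(0.2)
        assert reflect_unit(1.1) == pytest.approx(0.9)
        assert reflect_unit(-0.3) == pytest.approx(0.3)


class TestEligibilityAndSkips:
    def test_move_tail_skipped_on_two_leaf_tree(self, rng):
        net = parse_network("(A:1,B:1);")
        assert propose_move_tail(net, MoveConfig(), rng) is None

    def test_delete_skipped_on_tree(self, tree3, rng):
        assert propose_delete_reticulation(tree3, MoveConfig(), rng) is None

    def test_add_skipped_at_cap(self, net3_1ret, rng):
        cfg = MoveConfig(max_reticulations=1)
        assert propose_add_reticulation(net3_1ret, cfg, rng) is None

    def test_move_head_and_flip_need_reticulation(self, tree3, rng):
        cfg = MoveConfig()
        assert propose_move_head(tree3, cfg, rng) is None
        assert propose_flip_reticulation(tree3, cfg, rng) is None


class TestMoveMechanics:
    def test_move_tail_reaches_all_three_topologies(self, tree3, rng):
        cfg = MoveConfig()
        seen = set()
        for _ in range(200):
            res = propose_move_tail(tree3, cfg, rng)
            if res is not None and not validate(res.network):
                seen.add(canonical_topology_key(res.network))
        assert len(seen) == 3

    def test_move_head_preserves_gamma_and_count(self, net4_1ret, rng):
        cfg = MoveConfig()
        # the gamma pair is preserved; which edge is "designated" may flip
        pair = sorted(min(g, 1 - g)
                      for g in net4_1ret.inheritance().values())
        for _ in range(50):
            res = propose_move_head(net4_1ret, cfg, rng)
            assert res.network.num_reticulations == 1
            if not validate(res.network):
                got = sorted(min(g, 1 - g)
                             for g in res.network.inheritance().values())
                assert got == pytest.approx(pair)

    def test_flip_double_application_restores_topology(self, net4_1ret,
                                                       rng):
        cfg = MoveConfig()
        for _ in range(30):
            res = propose_flip_reticulation(net4_1ret, cfg, rng)
            if res is None or validate(res.network):
                continue
            back = propose_flip_reticulation(
                res.network, cfg, choices=dict(res.reverse))
            assert canonical_topology_key(back.network) == \
                canonical_topology_key(net4_1ret)
            assert res.network.num_reticulations == 1

    def test_add_then_delete_restores_tree(self, tree3, rng):
        cfg = MoveConfig(max_reticulations=3)
        for _ in range(40):
            res = propose_add_reticulation(tree3, cfg, rng)
            if validate(res.network):
                continue
            back = propose_delete_reticulation(
                res.network, cfg, choices=dict(res.reverse))
            assert canonical_topology_key(back.network) == \
                canonical_topology_key(tree3)
            # the RJ pair's acceptance terms cancel exactly
            assert res.log_hastings + res.log_jacobian \
                + back.log_hastings + back.log_jacobian == \
                pytest.approx(0.0, abs=1e-9)

    def test_delete_merges_lengths(self, net3_1ret):
        cfg = MoveConfig()
        elig = [(e.tail, e.head) for e in net3_1ret.reticulation_edges()
                if net3_1ret.indeg(e.tail) == 1
                and net3_1ret.outdeg(e.tail) == 2]
        res = propose_delete_reticulation(net3_1ret, cfg,
                                          choices={"edge": elig[0]})
        total_before = sum(e.length
                           for e in net3_1ret.edges.values())
        removed = res.choices["edge"]
        ell = res.reverse["length"]
        total_after = sum(e.length for e in res.network.edges.values())
        assert total_after == pytest.approx(total_before - ell, abs=1e-9)

    def test_same_edge_add_is_invalid_candidate(self, tree3):
        cfg = MoveConfig(max_reticulations=3)
        pair = next((e.tail, e.head) for e in tree3.edges.values()
                    if e.length >= 1.0)
        res = propose_add_reticulation(
            tree3, cfg, choices={"e1": pair, "e2": pair, "h1": 0.8,
                                 "h2": 0.2, "length": 0.5, "gamma": 0.5})
        kinds = {v.kind for v in validate(res.network)}
        assert kinds & {"cycle", "parallel-edge"}


class TestJacobianAndReversibility:
    def test_jacobian_zero_for_fixed_dimension_moves(self, rng):
        cfg = MoveConfig(max_reticulations=4)
        for _ in range(400):
            net = random_network(rng, int(rng.integers(3, 6)),
                                 int(rng.integers(0, 3)))
            kind, res = propose(net, cfg, rng)
            if res is None:
                continue
            if kind not in (ADD_RETICULATION, DELETE_RETICULATION):
                assert res.log_jacobian == 0.0

    def test_forward_reverse_pairs_are_exact(self, rng):
        """Every move's reconstructed reverse restores the state and
        exactly negates log_hastings + log_jacobian."""
        cfg = MoveConfig(max_reticulations=4)
        checked = Counter()
        trials = 0
        while trials < 1500 and (len(checked) < 7
                                 or min(checked.values()) < 25):
            trials += 1
            net = random_network(rng, int(rng.integers(3, 6)),
                                 int(rng.integers(0, 3)))
            kind, res = propose(net, cfg, rng)
            if res is None or validate(res.network):
                continue
            rev = _PROPOSERS[_PARTNER.get(kind, kind)](
                res.network, cfg, None, choices=dict(res.reverse))
            assert canonical_topology_key(rev.network) == \
                canonical_topology_key(net), kind
            total = (res.log_hastings + res.log_jacobian
                     + rev.log_hastings + rev.log_jacobian)
            assert total == pytest.approx(0.0, abs=1e-9), kind
            sig = sorted((round(e.length, 9),
                          None if e.gamma is None else round(e.gamma, 9))
                         for e in net.edges.values())
            sig2 = sorted((round(e.length, 9),
                           None if e.gamma is None else round(e.gamma, 9))
                          for e in rev.network.edges.values())
            assert sig == sig2, kind
            checked[kind] += 1
        assert len(checked) == 7, f"moves exercised: {dict(checked)}"
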