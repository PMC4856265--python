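"""Proposal moves for the trans-dimensional sampler over (network, gamma).

Seven moves are used.  Change-Length and Change-Inheritance perturb
continuous parameters only; Move-Tail, Move-Head and Flip-Reticulation
change the topology but not the model dimension; Add-Reticulation and
Delete-Reticulation change the dimension (reversible jump).  Move selection
is hierarchical: with probability ``kappa`` a dimension-changing move (Add
with probability ``kappa1``), otherwise with probability ``omega`` a
non-topology move (Change-Length with probability ``omega1``), otherwise a
topology move (``xi1 : xi2 : xi3`` for Move-Tail / Move-Head /
Flip-Reticulation).  On a tree the moves that require a reticulation are
unavailable and their mass is reassigned within the group: Add absorbs
Delete's share, Change-Length absorbs Change-Inheritance's, and Move-Tail
absorbs the whole topology group.

Topology-changing proposals may produce graphs that violate the network
definition (cycles, parallel edges, extra roots); such candidates are
returned as-is and die at the prior, which scores them -inf.  Proposals
whose eligible set is empty are skipped (``None``) and the iteration counts
as rejected, keeping the chain's kernel well defined.

Hastings ratios follow from the stated proposal densities: uniform choices
over eligible sets, uniform attachment heights along destination edges,
Exponential fresh edge lengths, Uniform(0,1) fresh inheritance
probabilities.  With attachment heights as the auxiliary variables, the
dimension-matching map for Add/Delete-Reticulation is a permutation-plus-
shear with unit Jacobian, so ``log_jacobian`` is 0 for every move; it is
carried separately because the acceptance rule distinguishes the terms.

Every move accepts an optional ``choices`` mapping that replays the move
deterministically (edges are identified by their (tail, head) node pair,
which is stable across copies); each :class:`ProposalResult` records the
``choices`` that reproduce it and the ``reverse`` choices that undo it,
which is how the test suite's reversibility harness verifies that
``log_hastings + log_jacobian`` of a forward/reverse pair is exactly
antisymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .likelihood import InheritanceMap
from .network import PhyloNetwork

__all__ = ["MoveConfig", "ProposalResult", "MOVES", "select_move",
           "selection_probs", "propose",
           "propose_change_length", "propose_change_inheritance",
           "propose_move_tail", "propose_move_head",
           "propose_flip_reticulation", "propose_add_reticulation",
           "propose_delete_reticulation"]

CHANGE_LENGTH = "change-length"
CHANGE_INHERITANCE = "change-inheritance"
MOVE_TAIL = "move-tail"
MOVE_HEAD = "move-head"
FLIP_RETICULATION = "flip-reticulation"
ADD_RETICULATION = "add-reticulation"
DELETE_RETICULATION = "delete-reticulation"

MOVES = (CHANGE_LENGTH, CHANGE_INHERITANCE, MOVE_TAIL, MOVE_HEAD,
         FLIP_RETICULATION, ADD_RETICULATION, DELETE_RETICULATION)


@dataclass
class MoveConfig:
    """Move-selection probabilities, proposal windows and caps.

    ``xi1 + xi2 + xi3`` must equal 1.  ``new_length_rate`` is the rate of
    the Exponential proposal for a freshly added reticulation edge's length
    (the sampler sets it equal to the branch-length prior rate so that part
    of the acceptance ratio cancels).  ``max_reticulations`` is a hard cap
    (the sampler defaults it to one less than the number of taxa).
    ``freeze_lengths`` is a validation mode realizing a finite
    topology-only state space: attachment points are taken at edge midpoints
    and all branch lengths are pinned at 1 after each topology move.
    """

    kappa: float = 0.2
    kappa1: float = 0.5
    omega: float = 0.55
    omega1: float = 0.7
    xi1: float = 1.0 / 3
    xi2: float = 1.0 / 3
    xi3: float = 1.0 / 3
    length_window: float = 0.5
    gamma_window: float = 0.1
    new_length_rate: float = 1.0
    max_reticulations: Optional[int] = None
    freeze_lengths: bool = False

    def __post_init__(self) -> None:
        for name in ("kappa", "kappa1", "omega", "omega1",
                     "xi1", "xi2", "xi3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(self.xi1 + self.xi2 + self.xi3 - 1.0) > 1e-9:
            raise ValueError("xi1 + xi2 + xi3 must equal 1")
        if self.length_window <= 0 or self.gamma_window <= 0:
            raise ValueError("proposal windows must be positive")
        if self.new_length_rate <= 0:
            raise ValueError("new_length_rate must be positive")


@dataclass
class ProposalResult:
    """A proposed state with the terms entering Green's acceptance ratio.

    The proposed network may be invalid (validity is the prior's job);
    ``log_jacobian`` is nonzero only for the dimension-changing moves (and
    is identically 0 under this parameterization, see module docstring).
    """

    network: PhyloNetwork
    log_hastings: float
    log_jacobian: float
    move: str
    choices: dict = field(default_factory=dict)
    reverse: dict = field(default_factory=dict)

    @property
    def proposed_gamma(self) -> InheritanceMap:
        return InheritanceMap.from_network(self.network)


# ----------------------------------------------------------------------
# move selection
# ----------------------------------------------------------------------

def selection_probs(net: PhyloNetwork, cfg: MoveConfig) -> dict[str, float]:
    """Per-state selection probability of each move under the hierarchical
    scheme (queryable for Hastings computations)."""
    tree = net.is_tree()
    p: dict[str, float] = dict.fromkeys(MOVES, 0.0)
    p[ADD_RETICULATION] = cfg.kappa * (1.0 if tree else cfg.kappa1)
    p[DELETE_RETICULATION] = 0.0 if tree else cfg.kappa * (1.0 - cfg.kappa1)
    non_dim = 1.0 - cfg.kappa
    p[CHANGE_LENGTH] = non_dim * cfg.omega * (1.0 if tree else cfg.omega1)
    p[CHANGE_INHERITANCE] = (0.0 if tree
                             else non_dim * cfg.omega * (1.0 - cfg.omega1))
    topo = non_dim * (1.0 - cfg.omega)
    if tree:
        p[MOVE_TAIL] = topo
    else:
        p[MOVE_TAIL] = topo * cfg.xi1
        p[MOVE_HEAD] = topo * cfg.xi2
        p[FLIP_RETICULATION] = topo * cfg.xi3
    return p


def select_move(net: PhyloNetwork, cfg: MoveConfig,
                rng: np.random.Generator) -> str:
    probs = selection_probs(net, cfg)
    u = rng.random()
    acc = 0.0
    for kind in MOVES:
        acc += probs[kind]
        if u < acc:
            return kind
    return CHANGE_LENGTH  # numerical guard; unreachable in practice


def _log_sel(net: PhyloNetwork, cfg: MoveConfig, kind: str) -> float:
    p = selection_probs(net, cfg)[kind]
    return math.log(p) if p > 0 else -math.inf


# ----------------------------------------------------------------------
# small helpers
# ----------------------------------------------------------------------

def reflect_nonnegative(x: float) -> float:
    """Reflect a perturbed branch length at 0."""
    return -x if x < 0 else x


def reflect_unit(x: float) -> float:
    """Reflect a perturbed probability into [0, 1]."""
    while x < 0.0 or x > 1.0:
        x = -x if x < 0.0 else 2.0 - x
    return x


def _edge_by_pair(net: PhyloNetwork, pair: tuple[int, int]):
    tail, head = pair
    for eid in net._out[tail]:
        if net.edges[eid].head == head:
            return net.edges[eid]
    raise KeyError(f"no edge {tail}->{head}")


def _resolve_edge(net: PhyloNetwork, ref):
    """Resolve an edge reference: an edge id or a (tail, head) node pair."""
    if isinstance(ref, tuple):
        return _edge_by_pair(net, ref)
    return net.edges[ref]


def _pair(e) -> tuple[int, int]:
    return (e.tail, e.head)


def _tail_eligible(net: PhyloNetwork) -> list[tuple[int, int]]:
    """Edges whose tail is a non-root internal tree node, as node pairs."""
    return sorted(_pair(e) for e in net.edges.values()
                  if net.indeg(e.tail) == 1 and net.outdeg(e.tail) == 2)


def _reticulation_pairs(net: PhyloNetwork) -> list[tuple[int, int]]:
    return sorted(_pair(e) for e in net.reticulation_edges())


def _delete_eligible(net: PhyloNetwork) -> list[tuple[int, int]]:
    """Reticulation edges whose tail is a non-root internal tree node:
    exactly the class Add-Reticulation creates, hence the deletable class."""
    return sorted(_pair(e) for e in net.reticulation_edges()
                  if net.indeg(e.tail) == 1 and net.outdeg(e.tail) == 2)


def _flip_eligible(net: PhyloNetwork) -> list[tuple[int, int]]:
    """Reticulation edges whose tail is a non-root internal tree node (the
    tail becomes the reticulation node after the flip; a root or
    reticulation tail would leave an ill-formed graph outright)."""
    return _delete_eligible(net)


# ----------------------------------------------------------------------
# moves 1-2: continuous perturbations (Hastings-neutral by symmetry)
# ----------------------------------------------------------------------

def propose_change_length(net: PhyloNetwork, cfg: MoveConfig,
                          rng: Optional[np.random.Generator] = None,
                          choices: Optional[dict] = None) -> ProposalResult:
    """Perturb a uniformly chosen edge's length by a symmetric uniform
    window reflected at 0; topology unchanged, Hastings-neutral."""
    if choices is None:
        assert rng is not None
        pairs = sorted(_pair(e) for e in net.edges.values())
        choices = {"edge": pairs[rng.integers(len(pairs))],
                   "delta": rng.uniform(-cfg.length_window,
                                        cfg.length_window)}
    cand = net.copy()
    e = _resolve_edge(cand, choices["edge"])
    old = e.length
    e.length = reflect_nonnegative(old + choices["delta"])
    reverse = {"edge": choices["edge"], "delta": old - e.length}
    return ProposalResult(cand, 0.0, 0.0, CHANGE_LENGTH, choices, reverse)


def propose_change_inheritance(net: PhyloNetwork, cfg: MoveConfig,
                               rng: Optional[np.random.Generator] = None,
                               choices: Optional[dict] = None
                               ) -> ProposalResult:
    """Perturb a uniformly chosen reticulation node's inheritance
    probability by a symmetric window reflected into [0, 1]; the partner
    edge keeps 1 - gamma."""
    rets = sorted(net.reticulation_nodes())
    if not rets:
        raise ValueError("change-inheritance requires a reticulation "
                         "(the selection scheme prevents this on trees)")
    if choices is None:
        assert rng is not None
        choices = {"node": rets[rng.integers(len(rets))],
                   "delta": rng.uniform(-cfg.gamma_window, cfg.gamma_window)}
    cand = net.copy()
    node = choices["node"]
    old = cand.inheritance()[node]
    new = reflect_unit(old + choices["delta"])
    cand.set_inheritance(node, new)
    reverse = {"node": node, "delta": old - new}
    return ProposalResult(cand, 0.0, 0.0, CHANGE_INHERITANCE, choices,
                          reverse)


# ----------------------------------------------------------------------
# move 3: Move-Tail
# ----------------------------------------------------------------------

def propose_move_tail(net: PhyloNetwork, cfg: MoveConfig,
                      rng: Optional[np.random.Generator] = None,
                      choices: Optional[dict] = None
                      ) -> Optional[ProposalResult]:
    """Relocate a tree node: detach the chosen edge at its tail, suppress
    the degree-2 remnant, and reattach onto a destination edge of the
    detached graph at a uniform height.  The candidate may be invalid
    (cycle, parallel edge, extra root) and is returned as-is."""
    elig = _tail_eligible(net)
    if not elig:
        return None
    n_elig = len(elig)
    if choices is None:
        assert rng is not None
        choices = {"edge": elig[rng.integers(n_elig)]}
    cand = net.copy()
    e = cand.remove_edge(_resolve_edge(cand, choices["edge"]).id)
    u, v = e.tail, e.head
    rev_h = cand.in_edges(u)[0].length  # height of the original attachment
    merged_id = cand.suppress(u)
    merged_len = cand.edges[merged_id].length

    dest_ids = sorted(cand.edges)  # the detached graph's edges
    n_dest = len(dest_ids)
    if "dest" not in choices:
        choices["dest"] = dest_ids[rng.integers(n_dest)]
    dest = cand.edges[merged_id] if choices["dest"] == "merged" \
        else _resolve_edge(cand, choices["dest"])
    dest_len = dest.length
    if "h" not in choices:
        choices["h"] = dest_len / 2.0 if cfg.freeze_lengths \
            else rng.uniform(0.0, dest_len)
    on_merged = dest.id == merged_id
    x = cand.subdivide(dest.id, choices["h"])
    cand.add_edge(x, v, e.length, e.gamma)
    if cfg.freeze_lengths:
        for ed in cand.edges.values():
            ed.length = 1.0
    lh = (_log_sel(cand, cfg, MOVE_TAIL) - _log_sel(net, cfg, MOVE_TAIL)
          + math.log(n_elig) - math.log(len(_tail_eligible(cand)))
          + math.log(n_dest) - math.log(len(cand.edges) - 2))
    if not cfg.freeze_lengths:
        lh += math.log(dest_len) - math.log(merged_len)
    # the reverse destination is the original position: the merged remnant
    # edge, which keeps its id in the candidate unless it was itself the
    # destination (then it is the edge the reverse detachment re-merges)
    reverse = {"edge": (x, v),
               "dest": "merged" if on_merged else merged_id, "h": rev_h}
    return ProposalResult(cand, lh, 0.0, MOVE_TAIL, choices, reverse)


# ----------------------------------------------------------------------
# move 4: Move-Head
# ----------------------------------------------------------------------

def propose_move_head(net: PhyloNetwork, cfg: MoveConfig,
                      rng: Optional[np.random.Generator] = None,
                      choices: Optional[dict] = None
                      ) -> Optional[ProposalResult]:
    """Relocate the head of a reticulation edge: suppress the old
    reticulation node and re-create it at a uniform height on a destination
    edge of the detached graph; the node's inheritance probability is
    preserved."""
    elig = _reticulation_pairs(net)
    if not elig:
        return None
    n_elig = len(elig)
    if choices is None:
        assert rng is not None
        choices = {"edge": elig[rng.integers(n_elig)]}
    cand = net.copy()
    e = cand.remove_edge(_resolve_edge(cand, choices["edge"]).id)
    u, v = e.tail, e.head
    gamma = e.gamma if e.gamma is not None else 0.5
    rev_h = cand.in_edges(v)[0].length
    # suppressing the old reticulation node: the partner edge loses its
    # reticulation status unless the merged edge still enters one
    merged_id = cand.suppress(v)
    merged_len = cand.edges[merged_id].length
    if not cand.is_reticulation(cand.edges[merged_id].head):
        cand.edges[merged_id].gamma = None

    dest_ids = sorted(cand.edges)
    n_dest = len(dest_ids)
    if "dest" not in choices:
        choices["dest"] = dest_ids[rng.integers(n_dest)]
    dest = cand.edges[merged_id] if choices["dest"] == "merged" \
        else _resolve_edge(cand, choices["dest"])
    dest_len = dest.length
    if "h" not in choices:
        choices["h"] = dest_len / 2.0 if cfg.freeze_lengths \
            else rng.uniform(0.0, dest_len)
    on_merged = dest.id == merged_id
    y = cand.subdivide(dest.id, choices["h"])
    cand.add_edge(u, y, e.length, gamma)
    for d in cand.in_edges(y):
        if d.gamma is None:
            d.gamma = 1.0 - gamma
    if cfg.freeze_lengths:
        for ed in cand.edges.values():
            ed.length = 1.0
    lh = (_log_sel(cand, cfg, MOVE_HEAD) - _log_sel(net, cfg, MOVE_HEAD)
          + math.log(n_elig) - math.log(len(_reticulation_pairs(cand)))
          + math.log(n_dest) - math.log(len(cand.edges) - 2))
    if not cfg.freeze_lengths:
        lh += math.log(dest_len) - math.log(merged_len)
    reverse = {"edge": (u, y),
               "dest": "merged" if on_merged else merged_id, "h": rev_h}
    return ProposalResult(cand, lh, 0.0, MOVE_HEAD, choices, reverse)


# ----------------------------------------------------------------------
# move 5: Flip-Reticulation
# ----------------------------------------------------------------------

def propose_flip_reticulation(net: PhyloNetwork, cfg: MoveConfig,
                              rng: Optional[np.random.Generator] = None,
                              choices: Optional[dict] = None
                              ) -> Optional[ProposalResult]:
    """Reverse the direction of a reticulation edge whose tail is a tree
    node: the tail becomes the reticulation node, the head becomes a tree
    node.  The flipped node's inheritance probability has no canonical
    owner, so a fresh gamma ~ Uniform(0,1) is drawn (density 1 both ways,
    Hastings-neutral)."""
    elig = _flip_eligible(net)
    if not elig:
        return None
    n_elig = len(elig)
    if choices is None:
        assert rng is not None
        choices = {"edge": elig[rng.integers(n_elig)],
                   "gamma": float(rng.random())}
    cand = net.copy()
    e = cand.remove_edge(_resolve_edge(cand, choices["edge"]).id)
    u, v = e.tail, e.head
    old_gamma = e.gamma if e.gamma is not None else 0.5
    cand.add_edge(v, u, e.length, choices["gamma"])
    # v is a tree node now: clear its remaining in-edge's annotation
    for d in cand.in_edges(v):
        d.gamma = None
    # u is the reticulation node now: partner edge gets 1 - gamma
    for d in cand.in_edges(u):
        if d.tail != v:
            d.gamma = 1.0 - choices["gamma"]
    lh = (_log_sel(cand, cfg, FLIP_RETICULATION)
          - _log_sel(net, cfg, FLIP_RETICULATION)
          + math.log(n_elig) - math.log(len(_flip_eligible(cand))))
    reverse = {"edge": (v, u), "gamma": old_gamma}
    return ProposalResult(cand, lh, 0.0, FLIP_RETICULATION, choices, reverse)


# ----------------------------------------------------------------------
# moves 6-7: Add / Delete-Reticulation (reversible jump)
# ----------------------------------------------------------------------

def propose_add_reticulation(net: PhyloNetwork, cfg: MoveConfig,
                             rng: Optional[np.random.Generator] = None,
                             choices: Optional[dict] = None
                             ) -> Optional[ProposalResult]:
    """Insert a reticulation edge between two uniformly chosen edges, at
    uniform heights along each, with an Exponential fresh length and a
    Uniform(0,1) fresh inheritance probability.  Choosing the same edge
    twice is allowed and always yields an invalid candidate (parallel edge
    or cycle) that dies at the prior."""
    cap = cfg.max_reticulations
    if cap is not None and net.num_reticulations >= cap:
        return None
    pairs = sorted(_pair(e) for e in net.edges.values())
    n_edges = len(pairs)
    if choices is None:
        assert rng is not None
        p1 = pairs[rng.integers(n_edges)]
        p2 = pairs[rng.integers(n_edges)]
        choices = {"e1": p1, "e2": p2,
                   "h1": rng.uniform(0.0, _resolve_edge(net, p1).length),
                   "h2": rng.uniform(0.0, _resolve_edge(net, p2).length),
                   "length": float(rng.exponential(1.0 / cfg.new_length_rate)),
                   "gamma": float(rng.random())}
    cand = net.copy()
    L1 = _resolve_edge(cand, choices["e1"]).length
    L2 = _resolve_edge(cand, choices["e2"]).length
    if choices["e1"] != choices["e2"]:
        x = cand.subdivide(_resolve_edge(cand, choices["e1"]).id,
                           choices["h1"])
        y = cand.subdivide(_resolve_edge(cand, choices["e2"]).id,
                           choices["h2"])
    else:  # both attachment points on one edge: invalid by construction
        e = _resolve_edge(cand, choices["e1"])
        ha, hb = sorted((choices["h1"], choices["h2"]))
        first = cand.subdivide(e.id, ha)
        lower = cand.out_edges(first)[0]
        second = cand.subdivide(lower.id, hb - ha)
        x, y = ((first, second) if choices["h1"] <= choices["h2"]
                else (second, first))
    cand.add_edge(x, y, choices["length"], choices["gamma"])
    for d in cand.in_edges(y):
        if d.gamma is None:
            d.gamma = 1.0 - choices["gamma"]
    rate = cfg.new_length_rate
    lh = ((_log_sel(cand, cfg, DELETE_RETICULATION)
           - math.log(len(_delete_eligible(cand))))
          - (_log_sel(net, cfg, ADD_RETICULATION)
             - 2.0 * math.log(n_edges)
             - math.log(L1) - math.log(L2)
             + math.log(rate) - rate * choices["length"]))
    reverse = {"edge": (x, y)}
    return ProposalResult(cand, lh, 0.0, ADD_RETICULATION, choices, reverse)


def propose_delete_reticulation(net: PhyloNetwork, cfg: MoveConfig,
                                rng: Optional[np.random.Generator] = None,
                                choices: Optional[dict] = None
                                ) -> Optional[ProposalResult]:
    """Remove a reticulation edge (chosen uniformly among those whose tail
    is a tree node), suppressing the two degree-2 remnants; lengths of
    merged edges add, the inheritance probability is discarded."""
    elig = _delete_eligible(net)
    if not elig:
        return None
    if choices is None:
        assert rng is not None
        choices = {"edge": elig[rng.integers(len(elig))]}
    cand = net.copy()
    e = cand.remove_edge(_resolve_edge(cand, choices["edge"]).id)
    x, y = e.tail, e.head
    # reticulation-node side first, then the tail side (never adjacent in a
    # valid network: coincidence would imply a parallel edge or cycle)
    rev_h2 = cand.in_edges(y)[0].length
    m2 = cand.suppress(y)
    if cand.edges[m2].head not in cand.reticulation_nodes():
        cand.edges[m2].gamma = None
    rev_h1 = cand.in_edges(x)[0].length
    m1 = cand.suppress(x)
    L1 = cand.edges[m1].length
    L2 = cand.edges[m2].length
    rate = cfg.new_length_rate
    n_edges_after = len(cand.edges)
    lh = ((_log_sel(cand, cfg, ADD_RETICULATION)
           - 2.0 * math.log(n_edges_after)
           - math.log(L1) - math.log(L2)
           + math.log(rate) - rate * e.length)
          - (_log_sel(net, cfg, DELETE_RETICULATION)
             - math.log(len(elig))))
    reverse = {"e1": _pair(cand.edges[m1]), "e2": _pair(cand.edges[m2]),
               "h1": rev_h1, "h2": rev_h2,
               "length": e.length,
               "gamma": e.gamma if e.gamma is not None else 0.5}
    return ProposalResult(cand, lh, 0.0, DELETE_RETICULATION, choices,
                          reverse)


# ----------------------------------------------------------------------
# dispatcher
# ----------------------------------------------------------------------

_PROPOSERS = {
    CHANGE_LENGTH: propose_change_length,
    CHANGE_INHERITANCE: propose_change_inheritance,
    MOVE_TAIL: propose_move_tail,
    MOVE_HEAD: propose_move_head,
    FLIP_RETICULATION: propose_flip_reticulation,
    ADD_RETICULATION: propose_add_reticulation,
    DELETE_RETICULATION: propose_delete_reticulation,
}


def propose(net: PhyloNetwork, cfg: MoveConfig,
            rng: np.random.Generator) -> tuple[str, Optional[ProposalResult]]:
    """Select a move and apply it; ``None`` result means the move was
    skipped (empty eligible set or reticulation cap) and the iteration
    counts as rejected."""
    kind = select_move(net, cfg, rng)
    return kind, _PROPOSERS[kind](net, cfg, rng)
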