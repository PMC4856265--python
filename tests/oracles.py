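"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different routes than the
package: the lineage-count transition probability via a matrix exponential
of the pure-death coalescent generator (vs the package's closed-form
alternating sum), the gene-tree topology probability on *trees* via explicit
Degnan-Salter coalescent-history enumeration (vs the package's
configuration dynamic program), and network isomorphism via brute-force
node bijections (vs canonical keys).
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from scipy.linalg import expm


# ----------------------------------------------------------------------
# g_{u,v}(t) via the pure-death generator
# ----------------------------------------------------------------------

def gcoal_expm(u: int, v: int, t: float) -> float:
    """P(u lineages -> v lineages in time t) from expm of the death chain
    with rate C(k,2) from state k to k-1."""
    if math.isinf(t):
        return 1.0 if v == 1 else 0.0
    Q = np.zeros((u, u))  # states 1..u
    for k in range(2, u + 1):
        rate = k * (k - 1) / 2.0
        Q[k - 1, k - 1] = -rate
        Q[k - 1, k - 2] = rate
    P = expm(Q * t)
    return float(P[u - 1, v - 1])


# ----------------------------------------------------------------------
# MSC gene-tree topology probability on trees by history enumeration
# ----------------------------------------------------------------------

class _SpeciesTree:
    """Rooted binary species tree parsed from nested tuples with branch
    lengths: ((('A', tA), ('B', tB)), t_int) style is clumsy, so the ctor
    takes (shape, lengths) where shape is nested tuples of names and
    lengths maps frozenset(cluster) -> branch length (root cluster maps to
    inf implicitly)."""

    def __init__(self, shape, lengths: dict):
        self.children: dict[frozenset, tuple] = {}
        self.lengths = dict(lengths)

        def build(x) -> frozenset:
            if isinstance(x, str):
                return frozenset([x])
            kids = [build(c) for c in x]
            clu = frozenset().union(*kids)
            self.children[clu] = tuple(kids)
            return clu

        self.root = build(shape)
        self.clusters = [frozenset([t]) for t in sorted(self.root)] + \
            sorted(self.children, key=lambda c: (len(c), sorted(c)))

    def is_ancestor(self, a: frozenset, b: frozenset) -> bool:
        return b <= a


def _forest_linear_extensions(events: list[frozenset]) -> int:
    """Number of orderings of the merger events (each a gene clade formed
    within one species branch) consistent with containment."""
    if not events:
        return 1
    n = len(events)
    # subtree sizes in the containment forest
    total = math.factorial(n)
    for e in events:
        size = sum(1 for f in events if f <= e)
        total //= size
    return total


def msc_gene_topology_prob(stree: _SpeciesTree, gene_nested,
                           taxon_map=None) -> float:
    """Exact P(gene-tree topology | species tree) by summing over all
    coalescent histories (assignments of gene-tree coalescences to species
    branches)."""
    taxon_map = taxon_map or {}

    gene_children: dict[frozenset, tuple] = {}

    def gbuild(x) -> frozenset:
        if isinstance(x, str):
            return frozenset([x])
        kids = [gbuild(c) for c in x]
        clu = frozenset().union(*kids)
        gene_children[clu] = tuple(kids)
        return clu

    groot = gbuild(gene_nested)
    gnodes = sorted(gene_children, key=lambda c: (len(c), sorted(c)))

    def species_of(allele_set: frozenset) -> frozenset:
        return frozenset(taxon_map.get(a, a) for a in allele_set)

    # candidate species branches for each gene node: cluster must contain
    # the gene clade's species; "branch" = the branch above that cluster,
    # root cluster = the infinite root branch
    candidates = {
        v: [c for c in stree.clusters
            if species_of(v) <= c and (c in stree.children
                                       or len(c) == 1 or c == stree.root)]
        for v in gnodes}

    # lineages entering each species branch before any coalescence:
    alleles = sorted(groot)
    entering_leaves: dict[frozenset, int] = {}
    for c in stree.clusters:
        entering_leaves[c] = sum(
            1 for a in alleles if taxon_map.get(a, a) in c)

    total = 0.0
    assignment: dict[frozenset, frozenset] = {}

    def recurse(i: int):
        nonlocal total
        if i == len(gnodes):
            total += _history_prob(stree, gene_children, assignment,
                                   entering_leaves, alleles, taxon_map)
            return
        v = gnodes[i]
        for c in candidates[v]:
            # respect gene-tree ancestry: children events must be on
            # descendant-or-equal branches
            ok = True
            for kid in gene_children[v]:
                if kid in assignment and not stree.is_ancestor(
                        c, assignment[kid]) and assignment[kid] != c:
                    ok = False
            if ok:
                assignment[v] = c
                recurse(i + 1)
                del assignment[v]

    recurse(0)
    return total


def _history_prob(stree, gene_children, assignment, entering_leaves,
                  alleles, taxon_map) -> float:
    # events per species branch
    events: dict[frozenset, list] = {c: [] for c in stree.clusters}
    for v, c in assignment.items():
        # verify ancestry constraint strictly (children assigned below)
        events[c].append(v)

    # check feasibility: an event's children must have fully entered the
    # branch: guaranteed by candidate filtering + ancestry check
    # lineages entering branch above cluster c:
    entering: dict[frozenset, int] = {}
    prob = 1.0
    for c in stree.clusters:  # leaves/small first
        if len(c) == 1 and c not in stree.children:
            u = entering_leaves[c]
        else:
            u = 0
            for kid in stree.children[c]:
                u += entering[kid] - len(events[kid])
        entering[c] = u
        k = len(events[c])
        if k > max(0, u - 1) and c != stree.root:
            return 0.0
        v_exit = u - k
        if c == stree.root:
            t = math.inf
            if v_exit != 1 and u > 0:
                return 0.0
            if u == 0:
                continue
            g = 1.0
        else:
            t = stree.lengths[c]
            if u == 0:
                continue
            g = gcoal_expm(u, v_exit, t)
        d = 1.0
        for kk in range(v_exit + 1, u + 1):
            d *= kk * (kk - 1) / 2.0
        w = _forest_linear_extensions(events[c])
        # w counts orderings; but orderings of INDEPENDENT events also
        # multiply -- _forest_linear_extensions already counts all linear
        # extensions of the containment forest
        prob *= g * w / d
    return prob


# ----------------------------------------------------------------------
# brute-force network isomorphism
# ----------------------------------------------------------------------

def networks_isomorphic(a, b) -> bool:
    """Leaf-label-preserving digraph isomorphism by trying all bijections
    over internal nodes (small networks only)."""
    la = {n: name for n, name in a.leaf_name.items()}
    lb = {name: n for n, name in b.leaf_name.items()}
    if sorted(la.values()) != sorted(b.leaf_name.values()):
        return False
    ia = [n for n in a.nodes if n not in a.leaf_name]
    ib = [n for n in b.nodes if n not in b.leaf_name]
    if len(ia) != len(ib) or len(a.edges) != len(b.edges):
        return False
    ea = {(e.tail, e.head) for e in a.edges.values()}
    eb = {(e.tail, e.head) for e in b.edges.values()}
    base = {n: lb[name] for n, name in la.items()}
    for perm in permutations(ib):
        mapping = dict(base)
        mapping.update(dict(zip(ia, perm)))
        if all((mapping[t], mapping[h]) in eb for t, h in ea):
            return True
    return False
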