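"""Exact probability of rooted gene-tree topologies under the multispecies
network coalescent (MSNC), and the multi-locus log-likelihood.

Backward in time, the lineages of a locus enter the network at its leaves,
coalesce within each branch at rate C(k,2) per coalescent unit, and at each
reticulation node every surviving lineage independently tracks one of the two
parent edges with that edge's inheritance probability.  The probability of
observing a given rooted gene-tree topology is the sum, over all assignments
of lineages to parent edges at reticulation nodes and over all coalescent
histories consistent with the topology, of products of

* per-branch lineage-count transition probabilities ``g_{u,v}(t)`` (Tavare),
* per-branch combinatorial weights ``w/d_{u,v}`` counting the orderings of
  the branch's coalescences that realize the topology among all equally
  likely orderings, and
* per-reticulation inheritance factors ``gamma^a (1-gamma)^b``.

The implementation is an exact dynamic program over "configurations" (the
multiset of uncoalesced gene lineages present on a branch), joint across
branches so that the correlation induced by reticulation splits is carried
exactly.  Complexity is exponential in the reticulation count and lineage
count, which is exact and fast at the scale this package targets (<= 8 taxa,
<= 3 reticulations).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence, Union

from .network import PhyloNetwork, parse_network

__all__ = [
    "GeneTreeTopology",
    "GeneTreeData",
    "InheritanceMap",
    "coalescence_prob",
    "gene_tree_mass",
    "locus_likelihood",
    "data_loglikelihood",
    "enumerate_topologies",
]


# ----------------------------------------------------------------------
# gene-tree topologies
# ----------------------------------------------------------------------

Nested = Union[str, tuple]


class GeneTreeTopology:
    """A rooted binary leaf-labelled topology, stored as clade bitmasks.

    Two instances compare equal iff they have the same leaf set and the same
    clade set.  Instances are immutable and hashable, so multisets of
    bootstrap topologies deduplicate naturally.
    """

    __slots__ = ("taxa", "bit", "children", "root_mask", "_hash",
                 "_transitions")

    def __init__(self, taxa: Sequence[str],
                 children: Mapping[int, tuple[int, int]]):
        self.taxa = tuple(sorted(taxa))
        self.bit = {name: 1 << i for i, name in enumerate(self.taxa)}
        self.children = dict(children)
        self.root_mask = (1 << len(self.taxa)) - 1
        self._hash = hash((self.taxa, frozenset(self.children)))
        self._transitions: dict = {}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_nested(cls, nested: Nested) -> "GeneTreeTopology":
        taxa: list[str] = []

        def collect(x: Nested):
            if isinstance(x, str):
                taxa.append(x)
            else:
                for y in x:
                    collect(y)

        collect(nested)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate leaf labels in gene tree")
        bit = {name: 1 << i for i, name in enumerate(sorted(taxa))}
        children: dict[int, tuple[int, int]] = {}

        def build(x: Nested) -> int:
            if isinstance(x, str):
                return bit[x]
            if len(x) != 2:
                raise ValueError("gene trees must be binary")
            a, b = build(x[0]), build(x[1])
            children[a | b] = (a, b)
            return a | b

        build(nested)
        return cls(sorted(taxa), children)

    @classmethod
    def from_newick(cls, text: str) -> "GeneTreeTopology":
        """Parse a rooted (binary) Newick gene tree; branch lengths and
        internal labels are ignored."""
        net = parse_network(text)
        if not net.is_tree():
            raise ValueError("gene trees may not contain reticulations")
        return cls.from_network_tree(net)

    @classmethod
    def from_network_tree(cls, net: PhyloNetwork) -> "GeneTreeTopology":
        names = sorted(net.leaf_name.values())
        bit = {name: 1 << i for i, name in enumerate(names)}
        children: dict[int, tuple[int, int]] = {}

        def walk(node: int) -> int:
            if net.is_leaf(node):
                return bit[net.leaf_name[node]]
            kids = [walk(e.head) for e in net.out_edges(node)]
            if len(kids) != 2:
                raise ValueError("gene trees must be binary")
            children[kids[0] | kids[1]] = (kids[0], kids[1])
            return kids[0] | kids[1]

        walk(net.root())
        return cls(names, children)

    # -- views ----------------------------------------------------------
    def clades(self) -> set[frozenset[str]]:
        def names(mask: int) -> frozenset[str]:
            return frozenset(t for t in self.taxa if self.bit[t] & mask)
        return {names(m) for m in self.children}

    def nested(self) -> Nested:
        def walk(mask: int) -> Nested:
            if mask not in self.children:
                return next(t for t in self.taxa if self.bit[t] == mask)
            a, b = self.children[mask]
            xa, xb = walk(a), walk(b)
            return tuple(sorted((xa, xb), key=str))
        return walk(self.root_mask)

    def newick(self) -> str:
        def walk(x: Nested) -> str:
            if isinstance(x, str):
                return x
            return "(" + ",".join(walk(y) for y in x) + ")"
        return walk(self.nested()) + ";"

    def __eq__(self, other) -> bool:
        return (isinstance(other, GeneTreeTopology)
                and self.taxa == other.taxa
                and self.children.keys() == other.children.keys())

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneTreeTopology({self.newick()!r})"

    # -- coalescence machinery ------------------------------------------
    def transitions(self, config: tuple[int, ...]):
        """All ways the lineages in ``config`` can coalesce within one
        branch: list of ``(exit_config, j, w)`` where ``j`` mergers occurred
        and ``w`` counts the ordered merger sequences realizing the exit
        (the linear extensions of the merger sub-forest)."""
        cached = self._transitions.get(config)
        if cached is not None:
            return cached
        levels: list[dict[tuple[int, ...], int]] = [{config: 1}]
        children = self.children
        while True:
            nxt: dict[tuple[int, ...], int] = {}
            for cfg, cnt in levels[-1].items():
                s = set(cfg)
                for parent, (c1, c2) in children.items():
                    if c1 in s and c2 in s:
                        new = tuple(sorted((s - {c1, c2}) | {parent}))
                        nxt[new] = nxt.get(new, 0) + cnt
            if not nxt:
                break
            levels.append(nxt)
        out = []
        for j, lev in enumerate(levels):
            for cfg, w in lev.items():
                out.append((cfg, j, w))
        self._transitions[config] = out
        return out


def enumerate_topologies(labels: Iterable[str]) -> list[GeneTreeTopology]:
    """All (2n-3)!! rooted binary topologies on ``labels``."""
    labels = sorted(labels)
    if not labels:
        raise ValueError("need at least one label")
    shapes: list[Nested] = [labels[0]]
    for lab in labels[1:]:
        nxt: list[Nested] = []
        for s in shapes:
            nxt.extend(_insert_everywhere(s, lab))
        shapes = nxt
    return [GeneTreeTopology.from_nested(s) for s in shapes]


def _insert_everywhere(shape: Nested, lab: str) -> list[Nested]:
    out: list[Nested] = [(shape, lab)]
    if isinstance(shape, tuple):
        a, b = shape
        out.extend((x, b) for x in _insert_everywhere(a, lab))
        out.extend((a, x) for x in _insert_everywhere(b, lab))
    return out


# ----------------------------------------------------------------------
# coalescent transition probability
# ----------------------------------------------------------------------

_MAX_LINEAGES = 12


@lru_cache(maxsize=262144)
def coalescence_prob(u: int, v: int, t: float) -> float:
    """Tavare's ``g_{u,v}(t)``: the probability that ``u`` lineages entering
    a population branch of length ``t`` coalescent units leave it as ``v``
    lineages.  ``t`` may be ``math.inf`` (a root edge).

    Raises a domain error unless ``1 <= v <= u``; beyond ``u = 12`` lineages
    the alternating sum is refused rather than silently degraded (never
    reached at the scale this package targets).
    """
    if not 1 <= v <= u:
        raise ValueError(f"need 1 <= v <= u, got u={u}, v={v}")
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if u > _MAX_LINEAGES:
        raise ValueError(f"coalescence_prob supports u <= {_MAX_LINEAGES}")
    if u == v == 1:
        return 1.0
    if t == 0:
        return 1.0 if u == v else 0.0
    if math.isinf(t):
        return 1.0 if v == 1 else 0.0
    terms = []
    for k in range(v, u + 1):
        rate = k * (k - 1) / 2.0
        coef = ((2 * k - 1) * (-1.0) ** (k - v)
                / (math.factorial(v) * math.factorial(k - v) * (v + k - 1)))
        prod = 1.0
        for y in range(k):
            prod *= (v + y) * (u - y) / (u + y)
        terms.append(math.exp(-rate * t) * coef * prod)
    val = math.fsum(terms)
    # the alternating sum can stray marginally outside [0, 1] at tiny t
    return min(1.0, max(0.0, val))


@lru_cache(maxsize=None)
def _orderings_denominator(u: int, v: int) -> float:
    """Number of distinct sequences of pairwise coalescences taking ``u``
    lineages down to ``v``: prod_{k=v+1}^{u} C(k, 2)."""
    d = 1.0
    for k in range(v + 1, u + 1):
        d *= k * (k - 1) / 2.0
    return d


# ----------------------------------------------------------------------
# inheritance probabilities
# ----------------------------------------------------------------------

@dataclass
class InheritanceMap:
    """One inheritance probability per reticulation node, shared across all
    loci: the probability that a lineage entering the node tracks the
    designated first parent edge (the partner edge receives ``1 - gamma``)."""

    gamma: dict[int, float] = field(default_factory=dict)

    @classmethod
    def from_network(cls, net: PhyloNetwork) -> "InheritanceMap":
        return cls(dict(net.inheritance()))

    def apply_to(self, net: PhyloNetwork) -> None:
        for node, g in self.gamma.items():
            net.set_inheritance(node, g)

    def check(self) -> None:
        for node, g in self.gamma.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gamma for node {node} outside [0,1]: {g}")


# ----------------------------------------------------------------------
# the MSNC mass function
# ----------------------------------------------------------------------

def gene_tree_mass(net: PhyloNetwork, g: GeneTreeTopology,
                   taxon_map: Optional[Mapping[str, str]] = None,
                   inheritance: Optional[InheritanceMap] = None) -> float:
    """Probability of the rooted gene-tree topology ``g`` given the network.

    ``taxon_map`` sends each allele label of ``g`` to a species (leaf name)
    of the network; by default alleles are species.  ``inheritance``
    optionally overrides the gamma values stored on the network's
    reticulation edges.  Summing over all rooted binary topologies on the
    same allele set gives 1.
    """
    if inheritance is not None:
        inheritance.check()
        net = net.copy()
        inheritance.apply_to(net)

    species_alleles: dict[str, list[int]] = {}
    for allele in g.taxa:
        sp = taxon_map.get(allele, allele) if taxon_map else allele
        species_alleles.setdefault(sp, []).append(g.bit[allele])
    leaf_of_species = {name: nid for nid, name in net.leaf_name.items()}
    unmapped = set(species_alleles) - set(leaf_of_species)
    if unmapped:
        raise ValueError(f"alleles map to unknown species: {sorted(unmapped)}")

    for e in net.reticulation_edges():
        if e.gamma is None or not 0.0 <= e.gamma <= 1.0:
            raise ValueError(f"invalid inheritance probability on {e!r}")

    # Factorized configuration DP.  A "block" is a set of open edges whose
    # configurations are mutually dependent (they descend from a common
    # reticulation split), with a joint table: tuple of per-edge
    # configurations -> summed weight.  Edges in different blocks are
    # independent, so blocks are joined (cartesian product) only when their
    # edges meet at a node; for a tree every block holds a single edge and
    # the DP is the standard per-branch one.
    blocks: list[tuple[tuple[int, ...], dict[tuple, float]]] = []

    _push_memo: dict[tuple, dict] = {}

    def push_branch(edge, config) -> dict:
        """Within-branch coalescent along ``edge``: exit config -> factor.
        Memoized per evaluation: the reticulation loops revisit the same
        (edge, entering configuration) pair many times."""
        key = (edge.id, config)
        cached = _push_memo.get(key)
        if cached is not None:
            return cached
        u = len(config)
        if u == 0:
            out: dict[tuple[int, ...], float] = {(): 1.0}
        else:
            out = {}
            for exit_cfg, j, w in g.transitions(config):
                v = u - j
                p = (coalescence_prob(u, v, edge.length)
                     * w / _orderings_denominator(u, v))
                if p > 0.0:
                    out[exit_cfg] = out.get(exit_cfg, 0.0) + p
        _push_memo[key] = out
        return out

    def gather(child_ids: list[int]) -> tuple[tuple[int, ...], dict]:
        """Join and remove the blocks holding ``child_ids``; edges with no
        block are implicitly empty."""
        nonlocal blocks
        hit_idx = [i for i, b in enumerate(blocks)
                   if any(eid in b[0] for eid in child_ids)]
        hit = [blocks[i] for i in hit_idx]
        blocks = [b for i, b in enumerate(blocks) if i not in hit_idx]
        edges: tuple[int, ...] = ()
        table: dict[tuple, float] = {(): 1.0}
        for bedges, btab in hit:
            table = {row1 + row2: w1 * w2
                     for row1, w1 in table.items()
                     for row2, w2 in btab.items()}
            edges = edges + bedges
        return edges, table

    for node in reversed(net.topological_order()):
        if net.is_leaf(node):
            cfg0 = tuple(sorted(species_alleles.get(net.leaf_name[node], ())))
            if not cfg0:
                continue  # no samples from this species: inert branch
            in_edge = net.in_edges(node)[0]
            blocks.append(((in_edge.id,),
                           {(c,): f for c, f
                            in push_branch(in_edge, cfg0).items()}))
            continue

        child_ids = [e.id for e in net.out_edges(node)]
        edges, table = gather(child_ids)
        keep = [i for i, eid in enumerate(edges) if eid not in child_ids]
        drop = [i for i, eid in enumerate(edges) if eid in child_ids]
        kept_edges = tuple(edges[i] for i in keep)

        if net.indeg(node) == 0:  # root: everything left must coalesce
            new_table: dict[tuple, float] = {}
            for row, wt in table.items():
                cfg = tuple(sorted(c for i in drop for c in row[i]))
                u = len(cfg)
                if u > 0:
                    total = 0.0
                    for exit_cfg, j, w in g.transitions(cfg):
                        if len(exit_cfg) == 1:
                            total += w / _orderings_denominator(u, 1)
                    wt *= total
                ctx = tuple(row[i] for i in keep)
                new_table[ctx] = new_table.get(ctx, 0.0) + wt
            blocks.append((kept_edges, new_table))
        elif net.is_reticulation(node):
            e1, e2 = net.in_edges(node)
            g1 = e1.gamma if e1.gamma is not None else 0.5
            new_table = {}
            for row, wt in table.items():
                cfg = tuple(sorted(c for i in drop for c in row[i]))
                ctx = tuple(row[i] for i in keep)
                n_cfg = len(cfg)
                for bits in range(1 << n_cfg):
                    left = tuple(cfg[i] for i in range(n_cfg)
                                 if bits >> i & 1)
                    right = tuple(cfg[i] for i in range(n_cfg)
                                  if not bits >> i & 1)
                    split_w = (g1 ** len(left)
                               * (1.0 - g1) ** len(right))
                    if split_w == 0.0:
                        continue
                    for c1, f1 in push_branch(e1, left).items():
                        for c2, f2 in push_branch(e2, right).items():
                            key = ctx + (c1, c2)
                            new_table[key] = (new_table.get(key, 0.0)
                                              + wt * split_w * f1 * f2)
            blocks.append((kept_edges + (e1.id, e2.id), new_table))
        else:  # internal tree node
            in_edge = net.in_edges(node)[0]
            new_table = {}
            for row, wt in table.items():
                cfg = tuple(sorted(c for i in drop for c in row[i]))
                ctx = tuple(row[i] for i in keep)
                for exit_cfg, f in push_branch(in_edge, cfg).items():
                    key = ctx + (exit_cfg,)
                    new_table[key] = new_table.get(key, 0.0) + wt * f
            blocks.append((kept_edges + (in_edge.id,), new_table))

    mass = 1.0
    for edges, table in blocks:
        assert not edges, "unconsumed branch configurations"
        mass *= sum(table.values())
    return min(1.0, max(0.0, mass))


# ----------------------------------------------------------------------
# multi-locus likelihood
# ----------------------------------------------------------------------

class GeneTreeData:
    """Gene-tree input for inference: ``m`` loci, each a multiset of rooted
    topologies (e.g. 100 bootstrap estimates), plus an allele-to-species map
    (identity when one individual is sampled per species).

    Distinct topologies are pooled across loci so the mass function is
    evaluated once per distinct topology per likelihood call.
    """

    def __init__(self, loci: Sequence[Union[Counter, Iterable[GeneTreeTopology]]],
                 taxon_map: Optional[Mapping[str, str]] = None):
        if not loci:
            raise ValueError("need at least one locus")
        self.loci: list[Counter] = []
        for i, locus in enumerate(loci):
            c = locus if isinstance(locus, Counter) else Counter(locus)
            if not c:
                raise ValueError(f"locus {i} has no gene trees")
            self.loci.append(c)
        self.taxon_map = dict(taxon_map) if taxon_map else None

        pool: dict[GeneTreeTopology, int] = {}
        for c in self.loci:
            for topo in c:
                pool.setdefault(topo, len(pool))
        self.topologies: list[GeneTreeTopology] = sorted(
            pool, key=lambda t: t.newick())
        index = {t: i for i, t in enumerate(self.topologies)}
        #: per locus: list of (topology index, multiplicity), and total count
        self.locus_weights: list[tuple[list[tuple[int, int]], int]] = [
            ([(index[t], k) for t, k in c.items()], sum(c.values()))
            for c in self.loci]

    @classmethod
    def from_newick_loci(cls, loci: Sequence[Sequence[str]],
                         taxon_map: Optional[Mapping[str, str]] = None
                         ) -> "GeneTreeData":
        parsed = [[GeneTreeTopology.from_newick(s) for s in locus]
                  for locus in loci]
        return cls(parsed, taxon_map)

    @property
    def num_loci(self) -> int:
        return len(self.loci)

    def alleles(self) -> list[str]:
        out: set[str] = set()
        for t in self.topologies:
            out.update(t.taxa)
        return sorted(out)

    def species(self) -> list[str]:
        tm = self.taxon_map or {}
        return sorted({tm.get(a, a) for a in self.alleles()})

    def check_against(self, net: PhyloNetwork) -> None:
        missing = set(self.species()) - set(net.leaf_name.values())
        if missing:
            raise ValueError(
                f"species absent from the network: {sorted(missing)}")


def locus_likelihood(net: PhyloNetwork, locus: Union[Counter, Iterable],
                     taxon_map: Optional[Mapping[str, str]] = None,
                     inheritance: Optional[InheritanceMap] = None) -> float:
    """Likelihood of one locus: the unweighted arithmetic mean of the mass
    over the locus's bootstrap multiset (deduplicated with multiplicities,
    which leaves the value unchanged)."""
    c = locus if isinstance(locus, Counter) else Counter(locus)
    if not c:
        raise ValueError("empty locus")
    total = sum(c.values())
    acc = 0.0
    for topo, k in c.items():
        acc += k * gene_tree_mass(net, topo, taxon_map, inheritance)
    return acc / total


def data_loglikelihood(net: PhyloNetwork, data: GeneTreeData,
                       inheritance: Optional[InheritanceMap] = None) -> float:
    """Sum over loci of log locus likelihoods (the topology-data likelihood
    of the Bayesian model).  A locus whose likelihood underflows to zero
    yields ``-inf`` (a rejectable state), never an exception."""
    data.check_against(net)
    masses = [gene_tree_mass(net, t, data.taxon_map, inheritance)
              for t in data.topologies]
    total = 0.0
    for pairs, n in data.locus_weights:
        lik = math.fsum(masses[i] * k for i, k in pairs) / n
        if lik <= 0.0:
            return -math.inf
        total += math.log(lik)
    return total
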