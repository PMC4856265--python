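"""Rooted phylogenetic networks: data structure, validity, rich-Newick I/O,
canonical topology keys, and exhaustive topology enumeration.

A phylogenetic network is a rooted DAG whose leaves are bijectively labelled
by taxa.  Tree nodes have in-degree 1 and out-degree 2 (the root has in-degree
0), reticulation nodes have in-degree 2 and out-degree 1 and model
hybridization or other gene flow.  Every edge carries a branch length in
coalescent units (generations divided by effective population size); each of
the two edges entering a reticulation node additionally carries an
inheritance probability, the two summing to one.

Networks are serialized as extended ("rich") Newick: a reticulation node
appears twice under a shared ``#H`` tag, once with its subtree and once as a
bare reference, with an optional third colon field holding the inheritance
probability (``:length:support:gamma``; the support field is ignored).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

__all__ = [
    "Edge",
    "PhyloNetwork",
    "NetworkViolation",
    "NetworkParseError",
    "parse_network",
    "write_network",
    "validate",
    "canonical_topology_key",
    "enumerate_trees",
    "enumerate_networks",
    "count_topologies",
]

#: Default length assigned to branches whose length is absent from the input.
DEFAULT_BRANCH_LENGTH = 1.0

#: Enumeration guard for count_topologies (exhaustive generation beyond this
#: is infeasible; the configured fallback applies).
ENUM_MAX_LEAVES = 5
ENUM_MAX_RETICULATIONS = 2


class NetworkParseError(ValueError):
    """Malformed extended-Newick input."""


@dataclass
class NetworkViolation:
    """A single way in which a candidate graph fails the network definition.

    ``kind`` is one of ``cycle``, ``parallel-edge``, ``multiple-roots``,
    ``degree-violation`` or ``negative-length``.
    """

    kind: str
    detail: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NetworkViolation({self.kind}: {self.detail})"


class Edge:
    """Directed edge tail -> head with a branch length and, when the head is
    a reticulation node, an inheritance probability."""

    __slots__ = ("id", "tail", "head", "length", "gamma")

    def __init__(self, eid: int, tail: int, head: int, length: float,
                 gamma: Optional[float] = None):
        self.id = eid
        self.tail = tail
        self.head = head
        self.length = length
        self.gamma = gamma

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = "" if self.gamma is None else f", gamma={self.gamma:.3g}"
        return f"Edge({self.tail}->{self.head}, len={self.length:.3g}{g})"


class PhyloNetwork:
    """Mutable rooted phylogenetic network.

    Node identifiers are opaque integers; leaf names carry all external
    meaning.  The structure deliberately tolerates graphs that violate the
    network definition (extra roots, cycles, parallel edges): MCMC proposals
    produce such candidates and their invalidity is detected by
    :func:`validate`, not prevented here.
    """

    def __init__(self) -> None:
        self.leaf_name: dict[int, str] = {}
        self.edges: dict[int, Edge] = {}
        self._in: dict[int, list[int]] = {}
        self._out: dict[int, list[int]] = {}
        self._next_node = 0
        self._next_edge = 0

    # ------------------------------------------------------------------
    # construction primitives
    # ------------------------------------------------------------------
    def add_node(self, name: Optional[str] = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self._in[nid] = []
        self._out[nid] = []
        if name is not None:
            self.leaf_name[nid] = name
        return nid

    def add_edge(self, tail: int, head: int, length: float = DEFAULT_BRANCH_LENGTH,
                 gamma: Optional[float] = None) -> int:
        eid = self._next_edge
        self._next_edge += 1
        self.edges[eid] = Edge(eid, tail, head, length, gamma)
        self._out[tail].append(eid)
        self._in[head].append(eid)
        return eid

    def remove_edge(self, eid: int) -> Edge:
        e = self.edges.pop(eid)
        self._out[e.tail].remove(eid)
        self._in[e.head].remove(eid)
        return e

    def remove_node(self, nid: int) -> None:
        if self._in[nid] or self._out[nid]:
            raise ValueError("cannot remove node with incident edges")
        del self._in[nid]
        del self._out[nid]
        self.leaf_name.pop(nid, None)

    def copy(self) -> "PhyloNetwork":
        other = PhyloNetwork.__new__(PhyloNetwork)
        other.leaf_name = dict(self.leaf_name)
        other.edges = {eid: Edge(e.id, e.tail, e.head, e.length, e.gamma)
                       for eid, e in self.edges.items()}
        other._in = {n: list(v) for n, v in self._in.items()}
        other._out = {n: list(v) for n, v in self._out.items()}
        other._next_node = self._next_node
        other._next_edge = self._next_edge
        return other

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def nodes(self) -> Iterable[int]:
        return self._in.keys()

    def in_edges(self, nid: int) -> list[Edge]:
        return [self.edges[i] for i in self._in[nid]]

    def out_edges(self, nid: int) -> list[Edge]:
        return [self.edges[i] for i in self._out[nid]]

    def indeg(self, nid: int) -> int:
        return len(self._in[nid])

    def outdeg(self, nid: int) -> int:
        return len(self._out[nid])

    def roots(self) -> list[int]:
        return [n for n in self._in if not self._in[n]]

    def root(self) -> int:
        r = self.roots()
        if len(r) != 1:
            raise ValueError(f"network has {len(r)} roots")
        return r[0]

    def leaves(self) -> list[int]:
        return sorted(self.leaf_name, key=self.leaf_name.__getitem__)

    def species(self) -> list[str]:
        return sorted(self.leaf_name.values())

    def is_leaf(self, nid: int) -> bool:
        return nid in self.leaf_name

    def is_reticulation(self, nid: int) -> bool:
        return len(self._in[nid]) == 2

    def reticulation_nodes(self) -> list[int]:
        return [n for n in self._in if len(self._in[n]) == 2]

    def reticulation_edges(self) -> list[Edge]:
        """Edges whose head is a reticulation node."""
        return [e for e in self.edges.values() if self.is_reticulation(e.head)]

    @property
    def num_reticulations(self) -> int:
        return len(self.reticulation_nodes())

    def is_tree(self) -> bool:
        return self.num_reticulations == 0

    def inheritance(self) -> dict[int, float]:
        """One inheritance probability per reticulation node: that of its
        designated first parent edge (the incident edge with smaller id)."""
        out = {}
        for n in self.reticulation_nodes():
            eid = min(self._in[n])
            g = self.edges[eid].gamma
            out[n] = 0.5 if g is None else g
        return out

    def set_inheritance(self, node: int, gamma: float) -> None:
        """Set the designated parent edge's probability to ``gamma`` (the
        partner edge receives ``1 - gamma``)."""
        eids = sorted(self._in[node])
        if len(eids) != 2:
            raise ValueError("not a reticulation node")
        self.edges[eids[0]].gamma = gamma
        self.edges[eids[1]].gamma = 1.0 - gamma

    def topological_order(self) -> list[int]:
        """Nodes root-first; raises ValueError on a cycle."""
        indeg = {n: len(self._in[n]) for n in self._in}
        stack = [n for n, d in indeg.items() if d == 0]
        order: list[int] = []
        while stack:
            n = stack.pop()
            order.append(n)
            for eid in self._out[n]:
                h = self.edges[eid].head
                indeg[h] -= 1
                if indeg[h] == 0:
                    stack.append(h)
        if len(order) != len(self._in):
            raise ValueError("graph has a cycle")
        return order

    def clusters(self) -> dict[int, frozenset[str]]:
        """Set of leaf names reachable from each node (hardwired cluster)."""
        out: dict[int, frozenset[str]] = {}
        for n in reversed(self.topological_order()):
            if n in self.leaf_name:
                out[n] = frozenset((self.leaf_name[n],))
            else:
                out[n] = frozenset().union(
                    *(out[self.edges[eid].head] for eid in self._out[n]))
        return out

    # ------------------------------------------------------------------
    # surgery used by proposals and enumeration
    # ------------------------------------------------------------------
    def subdivide(self, eid: int, h: float) -> int:
        """Split edge ``eid`` at distance ``h`` from its tail; returns the id
        of the new degree-2 node.  Inheritance annotation stays on the lower
        half (whose head is unchanged)."""
        e = self.remove_edge(eid)
        x = self.add_node()
        self.add_edge(e.tail, x, h)
        self.add_edge(x, e.head, e.length - h, e.gamma)
        return x

    def suppress(self, nid: int) -> int:
        """Remove an in-degree-1/out-degree-1 node, merging its two incident
        edges (lengths add; the lower edge's inheritance annotation is
        kept).  Returns the merged edge's id."""
        if self.indeg(nid) != 1 or self.outdeg(nid) != 1:
            raise ValueError("suppress requires a degree-2 node")
        lower = self.remove_edge(self._out[nid][0])
        upper = self.remove_edge(self._in[nid][0])
        self.remove_node(nid)
        return self.add_edge(upper.tail, lower.head,
                             upper.length + lower.length, lower.gamma)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        try:
            return f"<PhyloNetwork {write_network(self)}>"
        except Exception:
            return (f"<PhyloNetwork nodes={len(self._in)} "
                    f"edges={len(self.edges)} (unwritable)>")


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate(net: PhyloNetwork) -> list[NetworkViolation]:
    """Check an arbitrary candidate graph against the network definition.

    Returns an empty list iff the graph is a valid binary phylogenetic
    network: single root of out-degree 2, leaves (1, 0), internal tree nodes
    (1, 2), reticulation nodes (2, 1), acyclic, no parallel edges, and no
    negative branch length.  Every violated condition is reported at least
    once; candidates produced by topology-changing proposals are scored by
    the prior as invalid (probability zero) based on this list.
    """
    v: list[NetworkViolation] = []
    roots = net.roots()
    if len(roots) > 1:
        v.append(NetworkViolation("multiple-roots", f"roots: {sorted(roots)}"))
    elif not roots and net.edges:
        v.append(NetworkViolation("cycle", "no in-degree-0 node"))

    try:
        net.topological_order()
    except ValueError:
        if not any(x.kind == "cycle" for x in v):
            v.append(NetworkViolation("cycle", "directed cycle present"))

    seen_pairs: set[tuple[int, int]] = set()
    for e in net.edges.values():
        if (e.tail, e.head) in seen_pairs:
            v.append(NetworkViolation("parallel-edge", f"{e.tail}->{e.head}"))
        seen_pairs.add((e.tail, e.head))
        if e.length < 0:
            v.append(NetworkViolation("negative-length",
                                      f"edge {e.tail}->{e.head}: {e.length}"))

    for n in net.nodes:
        din, dout = net.indeg(n), net.outdeg(n)
        if net.is_leaf(n):
            ok = (din, dout) == (1, 0)
        elif n in roots and len(roots) <= 1:
            ok = (din, dout) == (0, 2)
        else:
            ok = (din, dout) in ((1, 2), (2, 1))
        if not ok:
            name = net.leaf_name.get(n, n)
            v.append(NetworkViolation(
                "degree-violation", f"node {name}: indeg={din} outdeg={dout}"))
    return v


def is_valid(net: PhyloNetwork) -> bool:
    return not validate(net)


# ----------------------------------------------------------------------
# extended-Newick parsing
# ----------------------------------------------------------------------

def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "(),:;":
            tokens.append(c)
            i += 1
        else:
            j = i
            while j < n and text[j] not in "(),:;" and not text[j].isspace():
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        t = self.peek()
        if t is None:
            raise NetworkParseError("unexpected end of input")
        self.pos += 1
        return t

    def expect(self, tok: str) -> None:
        t = self.take()
        if t != tok:
            raise NetworkParseError(f"expected {tok!r}, found {t!r}")


def parse_network(text: str) -> PhyloNetwork:
    """Parse one extended-Newick string into a :class:`PhyloNetwork`.

    Reticulation nodes are ``#H``-tagged and must appear exactly twice, with
    exactly one occurrence carrying the subtree.  Missing branch lengths
    default to 1.0 coalescent units; missing inheritance probabilities
    default to 0.5/0.5.  Raises :class:`NetworkParseError` naming the
    offending token on malformed input.
    """
    p = _Parser(text)
    net = PhyloNetwork()
    # #H tag -> (node id, has_subtree)
    hybrids: dict[str, list] = {}

    def parse_clade(parent: Optional[int]) -> None:
        if p.peek() == "(":
            p.take()
            nid = net.add_node()
            parse_clade(nid)
            while p.peek() == ",":
                p.take()
                parse_clade(nid)
            p.expect(")")
            label = p.peek()
            has_label = label is not None and label not in "(),:;"
            name = p.take() if has_label else ""
            _attach(parent, nid, name, has_children=True)
        else:
            label = p.peek()
            if label is None or label in "(),:;":
                raise NetworkParseError(f"expected a label, found {label!r}")
            _attach(parent, None, p.take(), has_children=False)

    def _attach(parent: Optional[int], nid: Optional[int], name: str,
                has_children: bool) -> None:
        htag = None
        if "#" in name:
            base, _, tag = name.partition("#")
            if not tag:
                raise NetworkParseError(f"bad hybrid label {name!r}")
            htag, name = tag, base
        if htag is None:
            if not has_children:
                if not name:
                    raise NetworkParseError("leaf with empty label")
                nid = net.add_node(name)
            # internal-node labels carry no structural meaning; dropped
        else:
            rec = hybrids.get(htag)
            if rec is None:
                if nid is None:
                    nid = net.add_node()
                hybrids[htag] = rec = [nid, has_children, 1]
            else:
                if has_children:
                    if rec[1]:
                        raise NetworkParseError(
                            f"hybrid #{htag} defined with a subtree twice")
                    # re-home the parsed children onto the existing node
                    assert nid is not None
                    for eid in list(net._out[nid]):
                        e = net.remove_edge(eid)
                        net.add_edge(rec[0], e.head, e.length, e.gamma)
                    net.remove_node(nid)
                    rec[1] = True
                rec[2] += 1
            nid = rec[0]

        length, gamma = _parse_fields(p)
        if parent is not None:
            assert nid is not None
            net.add_edge(parent, nid,
                         DEFAULT_BRANCH_LENGTH if length is None else length,
                         gamma)

    def _parse_fields(p: _Parser):
        length = gamma = None
        if p.peek() == ":":
            p.take()
            fields: list[Optional[str]] = []
            cur: Optional[str] = None
            # length field (may be empty)
            if p.peek() not in (None, ":", ",", ")", ";"):
                cur = p.take()
            fields.append(cur)
            for _ in range(2):
                if p.peek() == ":":
                    p.take()
                    val = None
                    if p.peek() not in (None, ":", ",", ")", ";"):
                        val = p.take()
                    fields.append(val)
                else:
                    fields.append(None)
            try:
                if fields[0] is not None:
                    length = float(fields[0])
                if fields[2] is not None:
                    gamma = float(fields[2])
            except ValueError as exc:
                raise NetworkParseError(f"bad numeric field: {exc}") from exc
        return length, gamma

    parse_clade(None)
    if p.peek() == ":":  # tolerate a root length annotation
        _parse_fields(p)
    p.expect(";")
    if p.peek() is not None:
        raise NetworkParseError(f"trailing token {p.peek()!r}")

    for tag, (nid, has_sub, count) in hybrids.items():
        if count != 2:
            raise NetworkParseError(f"hybrid #{tag} appears {count} times")
        if not has_sub:
            raise NetworkParseError(f"hybrid #{tag} has no subtree")

    names = list(net.leaf_name.values())
    if len(set(names)) != len(names):
        dup = sorted(n for n in set(names) if names.count(n) > 1)
        raise NetworkParseError(f"duplicate leaf labels: {dup}")
    if not names:
        raise NetworkParseError("network has no labelled leaves")

    _fill_gammas(net)
    bad = validate(net)
    if bad:
        raise NetworkParseError(f"parsed graph is not a valid network: {bad}")
    return net


def _fill_gammas(net: PhyloNetwork) -> None:
    for n in net.reticulation_nodes():
        e1, e2 = net.in_edges(n)
        if e1.gamma is None and e2.gamma is None:
            e1.gamma, e2.gamma = 0.5, 0.5
        elif e1.gamma is None:
            e1.gamma = 1.0 - e2.gamma
        elif e2.gamma is None:
            e2.gamma = 1.0 - e1.gamma


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def write_network(net: PhyloNetwork, include_lengths: bool = True,
                  include_gammas: bool = True) -> str:
    """Serialize a valid network to extended Newick under a canonical child
    ordering (children sorted by the smallest leaf label below them), so the
    output is deterministic for isomorphic input with permuted node ids."""
    bad = validate(net)
    if bad:
        raise ValueError(f"cannot write invalid network: {bad}")
    clusters = net.clusters()
    htag: dict[int, int] = {}
    expanded: set[int] = set()

    def fields(e: Edge) -> str:
        s = ""
        if include_lengths:
            s += f":{e.length:.10g}"
        if include_gammas and e.gamma is not None:
            if not include_lengths:
                s += f":{e.length:.10g}"
            s += f"::{e.gamma:.10g}"
        return s

    def order_key(e: Edge):
        cl = clusters[e.head]
        return (min(cl), len(cl), sorted(cl))

    def sub(e: Edge) -> str:
        h = e.head
        if net.is_leaf(h):
            return net.leaf_name[h] + fields(e)
        if net.is_reticulation(h):
            if h not in htag:
                htag[h] = len(htag) + 1
            if h in expanded:
                return f"#H{htag[h]}" + fields(e)
            expanded.add(h)
            inner = sub(net.out_edges(h)[0])
            return f"({inner})#H{htag[h]}" + fields(e)
        kids = sorted(net.out_edges(h), key=order_key)
        return "(" + ",".join(sub(k) for k in kids) + ")" + fields(e)

    r = net.root()
    kids = sorted(net.out_edges(r), key=order_key)
    return "(" + ",".join(sub(k) for k in kids) + ");"


# ----------------------------------------------------------------------
# canonical topology key
# ----------------------------------------------------------------------

def canonical_topology_key(net: PhyloNetwork) -> str:
    """A string equal for two networks iff their leaf-labelled topologies are
    isomorphic, ignoring branch lengths and inheritance probabilities.

    Reticulation nodes are referenced by index; the key is minimized over all
    assignments of indices to reticulation nodes, which makes it an exact
    canonical form (verified against a brute-force isomorphism oracle in the
    test suite).  Practical networks have at most a handful of reticulations,
    so the factorial minimization is cheap; more than 6 raises.
    """
    bad = validate(net)
    if bad:
        raise ValueError(f"no canonical key for invalid network: {bad}")
    rets = net.reticulation_nodes()
    if len(rets) > 6:
        raise ValueError("canonical key supports at most 6 reticulations")

    def ser(node: int, idx: dict[int, int]) -> str:
        if net.is_leaf(node):
            return net.leaf_name[node]
        if node in idx:
            return f"#{idx[node]}"
        parts = sorted(ser(e.head, idx) for e in net.out_edges(node))
        return "(" + ",".join(parts) + ")"

    best: Optional[str] = None
    for perm in itertools.permutations(rets):
        idx = {r: i + 1 for i, r in enumerate(perm)}
        top = ser(net.root(), idx)
        refs = ";".join(
            f"#{i + 1}={ser(net.out_edges(r)[0].head, idx)}"
            for i, r in enumerate(perm))
        key = top + ("|" + refs if refs else "")
        if best is None or key < best:
            best = key
    assert best is not None
    return best


# ----------------------------------------------------------------------
# exhaustive enumeration and topology counting
# ----------------------------------------------------------------------

def _single_leaf(label: str) -> PhyloNetwork:
    net = PhyloNetwork()
    net.add_node(label)
    return net


def enumerate_trees(labels: Iterable[str]) -> list[PhyloNetwork]:
    """All distinct rooted binary leaf-labelled trees on ``labels`` (the
    (2n-3)!! trees), built by recursive leaf insertion.  Unit branch
    lengths."""
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one label")
    trees = [_single_leaf(labels[0])]
    for lab in labels[1:]:
        nxt: list[PhyloNetwork] = []
        for t in trees:
            # attach on every edge
            for eid in list(t.edges):
                t2 = t.copy()
                x = t2.subdivide(eid, t2.edges[eid].length / 2.0)
                t2.add_edge(x, t2.add_node(lab))
                nxt.append(t2)
            # attach above the root
            t2 = t.copy()
            r = t2.root()
            x = t2.add_node()
            t2.add_edge(x, r)
            t2.add_edge(x, t2.add_node(lab))
            nxt.append(t2)
        trees = nxt
    return trees


def _add_reticulation_everywhere(net: PhyloNetwork) -> Iterator[PhyloNetwork]:
    """Yield every (possibly invalid) candidate obtained by inserting one
    reticulation edge: tail point on any edge or above the root, head point
    on any other edge."""
    edge_ids = list(net.edges)
    for src in edge_ids + [None]:
        for tgt in edge_ids:
            if src == tgt:
                continue  # same-edge attachments are always invalid
            cand = net.copy()
            if src is None:
                old_root = cand.root()
                x = cand.add_node()
                cand.add_edge(x, old_root)
            else:
                x = cand.subdivide(src, cand.edges[src].length / 2.0)
            y = cand.subdivide(tgt, cand.edges[tgt].length / 2.0)
            cand.add_edge(x, y, DEFAULT_BRANCH_LENGTH)
            cand.set_inheritance(y, 0.5)
            yield cand


def enumerate_networks(labels: Iterable[str], m: int) -> list[PhyloNetwork]:
    """All distinct binary network topologies on ``labels`` with exactly
    ``m`` reticulation nodes, by exhaustive reticulation insertion with
    canonical-key deduplication.

    Every binary network with m reticulations contains a reticulation edge
    whose tail is a tree node or the root (take a reticulation node none of
    whose parents is a reticulation node); deleting it yields a network with
    m - 1 reticulations, so insertion from the (m-1)-enumeration (allowing a
    tail point above the root) is exhaustive.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    current: dict[str, PhyloNetwork] = {
        canonical_topology_key(t): t for t in enumerate_trees(labels)}
    for _ in range(m):
        nxt: dict[str, PhyloNetwork] = {}
        for net in current.values():
            for cand in _add_reticulation_everywhere(net):
                if not validate(cand):
                    key = canonical_topology_key(cand)
                    nxt.setdefault(key, cand)
        current = nxt
    return list(current.values())


_count_cache: dict[tuple[int, int], int] = {}


def count_topologies(n: int, m: int,
                     fallback: Optional[int] = None) -> int:
    """T_{n,m}: the number of distinct binary phylogenetic network topologies
    with ``n`` leaves and ``m`` reticulation nodes.

    Exact by exhaustive enumeration for n <= 5 and m <= 2.  Beyond the guard
    the configured ``fallback`` (typically 1, i.e. dropping the factor from
    the prior) is returned; with no fallback an unsupported-size error is
    raised.
    """
    if n < 2 or m < 0:
        raise ValueError("need n >= 2 leaves and m >= 0 reticulations")
    if n > ENUM_MAX_LEAVES or m > ENUM_MAX_RETICULATIONS:
        if fallback is not None:
            return fallback
        raise ValueError(
            f"T_({n},{m}) exceeds the enumeration guard "
            f"(n <= {ENUM_MAX_LEAVES}, m <= {ENUM_MAX_RETICULATIONS}) "
            "and no fallback is configured")
    key = (n, m)
    if key not in _count_cache:
        labels = [f"L{i}" for i in range(n)]
        if m == 0:
            # (2n-3)!! rooted binary trees; still run the enumeration so the
            # count is produced by generation + deduplication, then sanity
            # check against the closed form.
            trees = enumerate_trees(labels)
            keys = {canonical_topology_key(t) for t in trees}
            dfact = math.prod(range(2 * n - 3, 0, -2))
            assert len(keys) == dfact == len(trees)
            _count_cache[key] = len(keys)
        else:
            _count_cache[key] = len(enumerate_networks(labels, m))
    return _count_cache[key]
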