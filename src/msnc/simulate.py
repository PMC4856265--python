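"""Forward simulation under the multispecies network coalescent, sequence
evolution, and gene-tree re-estimation.

This module is both the Monte-Carlo oracle for the likelihood (simulated
topology frequencies must match the exact mass function) and the synthetic-
data factory for the validation study: gene trees are drawn within a model
network, 1000-site alignments are evolved along them under a (time-
reversible) substitution model with population mutation rate theta, and
per-locus bootstrap tree sets are re-estimated with neighbor joining,
mirroring how multi-locus data sets are assembled in practice.

Coalescent-unit to substitution-unit conversion: the expected number of
substitutions per site along a branch is (theta / 2) x (length in
coalescent units), the theta = 4 N mu convention with time in units of 2N
generations.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .likelihood import GeneTreeTopology
from .network import PhyloNetwork, parse_network, validate

__all__ = ["SimConfig", "GTRModel", "ModelNetworkSuite",
           "simulate_gene_tree", "simulate_alignment",
           "estimate_gene_trees", "rf_distance", "model_network_suite",
           "topology_from_clades"]

_BASES = "ACGT"


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class GTRModel:
    """General time-reversible substitution model.  The default (all
    exchangeabilities and frequencies equal) is Jukes-Cantor."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)  # AC AG AT CG CT GT
    frequencies: tuple = (0.25, 0.25, 0.25, 0.25)

    def rate_matrix(self) -> np.ndarray:
        r = self.exchangeabilities
        pi = np.asarray(self.frequencies, float)
        if len(r) != 6 or len(pi) != 4 or abs(pi.sum() - 1.0) > 1e-8 \
                or min(r) <= 0 or pi.min() <= 0:
            raise ValueError("invalid GTR parameters")
        S = np.zeros((4, 4))
        S[0, 1], S[0, 2], S[0, 3] = r[0], r[1], r[2]
        S[1, 2], S[1, 3], S[2, 3] = r[3], r[4], r[5]
        S = S + S.T
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to one expected substitution per unit branch length
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def transition(self, d: float) -> np.ndarray:
        """P(t) for branch length ``d`` expected substitutions per site."""
        from scipy.linalg import expm
        return expm(self.rate_matrix() * d)


@dataclass
class SimConfig:
    """Synthetic-data generation settings.

    Defaults mirror the validation study's regime: theta = 0.036, 1000
    sites per locus, 100 bootstrap replicates per locus.
    """

    loci: int = 128
    samples_per_species: Optional[Mapping[str, int]] = None
    theta: float = 0.036
    seq_length: int = 1000
    model: GTRModel = field(default_factory=GTRModel)
    bootstrap_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loci < 1:
            raise ValueError("need at least one locus")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.seq_length < 1:
            raise ValueError("need at least one site")


# ----------------------------------------------------------------------
# MSNC gene-tree simulation
# ----------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node", "elapsed")

    def __init__(self, node: int, elapsed: float = 0.0):
        self.node = node
        self.elapsed = elapsed


def simulate_gene_tree(net: PhyloNetwork,
                       samples_per_species: Optional[Mapping[str, int]],
                       rng: np.random.Generator) -> PhyloNetwork:
    """Draw one gene tree under the MSNC: within each branch lineages
    coalesce at rate C(k,2) per coalescent unit; at each reticulation node
    every surviving lineage independently tracks the first parent edge with
    that edge's inheritance probability; remaining lineages coalesce above
    the root.  Returns a rooted binary tree whose leaf names are allele
    labels (``<species>`` when one sample, ``<species>_<i>`` otherwise) and
    whose branch lengths are in coalescent units."""
    bad = validate(net)
    if bad:
        raise ValueError(f"invalid network: {bad}")
    spp = {name: 1 for name in net.leaf_name.values()}
    if samples_per_species:
        spp.update(samples_per_species)
    gt = PhyloNetwork()

    def coalesce_in(lineages: list[_Lineage], t: float) -> list[_Lineage]:
        k = len(lineages)
        tau = 0.0
        while k >= 2:
            w = rng.exponential(2.0 / (k * (k - 1)))
            if tau + w > t:
                break
            tau += w
            for lin in lineages:
                lin.elapsed += w
            i, j = sorted(rng.choice(k, size=2, replace=False))
            parent = gt.add_node()
            gt.add_edge(parent, lineages[i].node, lineages[i].elapsed)
            gt.add_edge(parent, lineages[j].node, lineages[j].elapsed)
            lineages[i] = _Lineage(parent)
            del lineages[j]
            k -= 1
        if math.isfinite(t):
            rest = t - tau
            for lin in lineages:
                lin.elapsed += rest
        return lineages

    # configurations at the top of each processed edge
    at_top: dict[int, list[_Lineage]] = {}
    for v in reversed(net.topological_order()):
        if net.is_leaf(v):
            name = net.leaf_name[v]
            count = spp.get(name, 1)
            labels = [name] if count == 1 else [
                f"{name}_{i + 1}" for i in range(count)]
            lineages = [_Lineage(gt.add_node(lab)) for lab in labels]
            e = net.in_edges(v)[0]
            at_top[e.id] = coalesce_in(lineages, e.length)
        elif net.indeg(v) == 0:  # root
            arrived = []
            for e in net.out_edges(v):
                arrived.extend(at_top.pop(e.id, []))
            final = coalesce_in(arrived, math.inf)
            assert len(final) <= 1
        elif net.is_reticulation(v):
            arrived = []
            for e in net.out_edges(v):
                arrived.extend(at_top.pop(e.id, []))
            e1, e2 = net.in_edges(v)
            g1 = e1.gamma if e1.gamma is not None else 0.5
            left = [lin for lin in arrived if rng.random() < g1]
            right = [lin for lin in arrived if lin not in left]
            at_top[e1.id] = coalesce_in(left, e1.length)
            at_top[e2.id] = coalesce_in(right, e2.length)
        else:  # internal tree node
            arrived = []
            for e in net.out_edges(v):
                arrived.extend(at_top.pop(e.id, []))
            e = net.in_edges(v)[0]
            at_top[e.id] = coalesce_in(arrived, e.length)
    return gt


# ----------------------------------------------------------------------
# sequence simulation
# ----------------------------------------------------------------------

def simulate_alignment(gene_tree: PhyloNetwork, cfg: SimConfig,
                       rng: np.random.Generator) -> dict[str, str]:
    """Evolve i.i.d. sites along the gene tree; the expected substitutions
    per site on a branch are (theta / 2) x coalescent-unit length."""
    Q_model = cfg.model
    pi = np.asarray(Q_model.frequencies, float)
    L = cfg.seq_length
    root = gene_tree.root()
    seqs: dict[int, np.ndarray] = {
        root: rng.choice(4, size=L, p=pi)}
    out: dict[str, str] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        state = seqs.pop(node)
        if gene_tree.is_leaf(node):
            out[gene_tree.leaf_name[node]] = "".join(
                _BASES[s] for s in state)
            continue
        for e in gene_tree.out_edges(node):
            d = 0.5 * cfg.theta * e.length
            P = Q_model.transition(d)
            child_state = np.empty(L, dtype=np.int64)
            for s in range(4):
                idx = np.nonzero(state == s)[0]
                if idx.size:
                    child_state[idx] = rng.choice(4, size=idx.size, p=P[s])
            seqs[e.head] = child_state
            stack.append(e.head)
    return out


# ----------------------------------------------------------------------
# gene-tree estimation (bootstrap + neighbor joining)
# ----------------------------------------------------------------------

def _jc_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Jukes-Cantor distances from an (n_taxa, n_sites) integer matrix;
    saturated pairs are capped."""
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (rows[i] != rows[i + 1:]).mean(axis=1)
        p = np.minimum(diff, 0.74)
        d[i, i + 1:] = -0.75 * np.log1p(-4.0 / 3.0 * p)
        d[i + 1:, i] = d[i, i + 1:]
    return d


def topology_from_clades(taxa: Sequence[str],
                         clades: Sequence[frozenset]) -> GeneTreeTopology:
    """Assemble a rooted binary topology from its set of nontrivial proper
    clades (the full set and singletons are implied)."""
    taxa = sorted(taxa)
    bit = {t: 1 << i for i, t in enumerate(taxa)}
    masks = sorted({sum(bit[x] for x in c) for c in clades})
    full = (1 << len(taxa)) - 1
    nodes = sorted(set(masks + [full] + [bit[t] for t in taxa]),
                   key=lambda m: (bin(m).count("1"), m))
    children: dict[int, tuple[int, int]] = {}
    for m in nodes:
        if bin(m).count("1") < 2:
            continue
        inside = [c for c in nodes if c != m and c & m == c]
        maximal = [c for c in inside
                   if not any(c != d and c & d == c for d in inside)]
        if len(maximal) != 2 or maximal[0] | maximal[1] != m:
            raise ValueError("clade set is not a binary rooted tree")
        children[m] = (maximal[0], maximal[1])
    return GeneTreeTopology(taxa, children)


def _root_at_outgroup(tree, taxa: list[str],
                      outgroup: str) -> GeneTreeTopology:
    """Read the rooted topology off an unrooted skbio TreeNode: each split's
    side not containing the outgroup is a rooted clade."""
    full = frozenset(taxa)
    clades: set[frozenset] = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if outgroup in side:
            side = full - side
        if 1 < len(side) < len(taxa) - 1:
            clades.add(side)
    clades.add(full - {outgroup})
    return topology_from_clades(taxa, sorted(clades, key=sorted))


def _nj_rooted_topology(dist: np.ndarray, taxa: list[str],
                        outgroup: str) -> GeneTreeTopology:
    """Neighbor joining (scikit-bio) followed by outgroup rooting."""
    return _root_at_outgroup(nj(DistanceMatrix(dist, ids=taxa)),
                             taxa, outgroup)


def _have_fasttree() -> bool:
    import shutil
    return shutil.which("fasttree") is not None


def _fasttree_topologies(rows_list: list[np.ndarray], taxa: list[str],
                         outgroup: str) -> list[GeneTreeTopology]:
    """Approximate-ML trees (FastTree, Jukes-Cantor, uniform rates) for a
    batch of alignments, rooted at the outgroup."""
    import io
    import subprocess
    lines: list[str] = []
    for rows in rows_list:
        lines.append(f" {len(taxa)} {rows.shape[1]}")
        for i, t in enumerate(taxa):
            lines.append(t + "  " + "".join(_BASES[x] for x in rows[i]))
    proc = subprocess.run(
        ["fasttree", "-nt", "-nocat", "-quiet", "-nosupport",
         "-n", str(len(rows_list))],
        input="\n".join(lines) + "\n", capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"fasttree failed: {proc.stderr[-500:]}")
    from skbio import TreeNode
    out = []
    for nwk in proc.stdout.strip().splitlines():
        out.append(_root_at_outgroup(TreeNode.read(io.StringIO(nwk)),
                                     taxa, outgroup))
    return out


def estimate_gene_trees(alignments: Sequence[Mapping[str, str]],
                        cfg: SimConfig, outgroup: str,
                        rng: np.random.Generator,
                        engine: str = "auto") -> list[Counter]:
    """Per locus: ``bootstrap_reps`` site-resampled replicates, each passed
    to the tree-estimation engine and rooted at the designated outgroup.

    ``engine`` is "fasttree" (approximate maximum likelihood via the
    external FastTree binary, mirroring how bootstrap gene trees are built
    in practice), "nj" (internal Jukes-Cantor + neighbor joining fallback),
    or "auto" (FastTree when the executable is available).  Returns one
    topology multiset per locus; no silent filtering (degenerate alignments
    yield whatever the engine produces)."""
    if not alignments:
        raise ValueError("no alignments given")
    if engine == "auto":
        engine = "fasttree" if _have_fasttree() else "nj"
    if engine not in ("fasttree", "nj"):
        raise ValueError(f"unknown engine {engine!r}")
    code = {b: i for i, b in enumerate(_BASES)}
    out: list[Counter] = []
    for li, aln in enumerate(alignments):
        taxa = sorted(aln)
        if outgroup not in taxa:
            raise ValueError(f"locus {li}: outgroup {outgroup!r} missing")
        try:
            rows = np.array([[code[c] for c in aln[t]] for t in taxa])
            L = rows.shape[1]
            boots = [rows[:, rng.integers(0, L, size=L)]
                     for _ in range(cfg.bootstrap_reps)]
            counter: Counter = Counter()
            if engine == "fasttree":
                for topo in _fasttree_topologies(boots, taxa, outgroup):
                    counter[topo] += 1
            else:
                for sub in boots:
                    d = _jc_distance_matrix(sub)
                    counter[_nj_rooted_topology(d, taxa, outgroup)] += 1
        except Exception as exc:
            raise RuntimeError(f"estimation failed for locus {li}: {exc}"
                               ) from exc
        out.append(counter)
    return out


# ----------------------------------------------------------------------
# tree comparison
# ----------------------------------------------------------------------

def rf_distance(t1: GeneTreeTopology, t2: GeneTreeTopology) -> float:
    """Normalized rooted Robinson-Foulds distance: the symmetric difference
    of the internal-edge-induced clusters divided by the total number of
    internal edges compared; 0 iff the topologies are identical, 1 when no
    cluster is shared."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees must share one leaf set")
    c1 = {m for m in t1.children if m != t1.root_mask}
    c2 = {m for m in t2.children if m != t2.root_mask}
    total = len(c1) + len(c2)
    if total == 0:
        return 0.0
    return len(c1 ^ c2) / total


# ----------------------------------------------------------------------
# the model-network suite
# ----------------------------------------------------------------------

NET_1RET = ("((((A:1.2,B:1.2):0.9,((C:0.8,D:0.8):0.8)#H1:0.5::0.5):1.0,"
            "((E:1.1,F:1.1):0.9,#H1:0.7::0.5):1.0):0.8,O:1.5);")

NET_2RET = ("((((A:1.2,(B:0.6)#H2:0.6::0.7):0.9,((C:0.8,D:0.8):0.8)"
            "#H1:0.5::0.5):1.0,((E:1.1,(#H2:0.9::0.3,F:0.6):0.5):0.9,"
            "#H1:0.7::0.5):1.0):0.8,O:1.5);")

NET_3RET = ("(((((A:1.2,(B:0.6)#H2:0.6::0.7):0.9,((C:0.8,D:0.8):0.8)"
            "#H1:0.5::0.5):0.5,#H3:0.9::0.25):0.5,(((E:0.7)#H3:0.6::0.75,"
            "(#H2:0.9::0.3,F:0.6):0.5):0.9,#H1:0.7::0.5):1.0):0.8,O:1.5);")


@dataclass
class ModelNetworkSuite:
    """Three 7-taxon model networks with 1, 2 and 3 reticulations, one
    designated outgroup (O) and branch lengths between 0.5 and 1.5
    coalescent units, fixed inheritance probabilities."""

    networks: tuple[PhyloNetwork, PhyloNetwork, PhyloNetwork]
    outgroup: str = "O"

    def __iter__(self):
        return iter(self.networks)


def model_network_suite() -> ModelNetworkSuite:
    """Deterministic construction of the three fixture networks."""
    nets = tuple(parse_network(s) for s in (NET_1RET, NET_2RET, NET_3RET))
    for i, net in enumerate(nets, start=1):
        assert not validate(net)
        assert net.num_reticulations == i
    return ModelNetworkSuite(nets)
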