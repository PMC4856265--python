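"""Metropolis-Hastings sampling of the (network, inheritance) posterior.

Each iteration selects a move, proposes a candidate, and accepts it with
probability min(1, r) where

    log r = (log-likelihood ratio) + (log-prior ratio)
            + log Hastings ratio (+ log |Jacobian| for the
              dimension-changing moves).

Candidates violating the network definition have prior zero and are always
rejected.  Samples from a burn-in period are discarded and the remainder is
thinned before storage.  Runs are bit-reproducible given (data, config,
seed).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .likelihood import GeneTreeData, data_loglikelihood
from .moves import MOVES, MoveConfig, propose
from .network import (PhyloNetwork, canonical_topology_key, parse_network,
                      validate, write_network)
from .priors import PriorConfig, log_prior_inheritance, log_prior_network

__all__ = ["RunConfig", "ChainRecord", "SampleChain", "run_chain",
           "credible_set", "trace_summary", "random_tree",
           "greedy_consensus_tree"]

_TOPOLOGY_MOVES = {"move-tail", "move-head", "flip-reticulation",
                   "add-reticulation", "delete-reticulation"}


@dataclass
class RunConfig:
    """Chain configuration.

    ``burn_in`` defaults to 10% of ``iterations``; ``thin`` defaults so
    that about 10^4 records are stored.  ``init`` selects the starting
    state: "consensus" (a greedy consensus tree of the input gene trees;
    falls back to random when a nontrivial allele map is present) or
    "random"; ``init_network`` overrides both with an explicit extended-
    Newick string.  ``cache_likelihood`` memoizes log-likelihoods keyed by
    the serialized state, worthwhile only when the chain revisits states
    exactly (e.g. the frozen-lengths validation mode).
    """

    iterations: int = 5_000_000
    burn_in: Optional[int] = None
    thin: Optional[int] = None
    seed: int = 0
    prior: PriorConfig = field(default_factory=PriorConfig)
    moves: MoveConfig = field(default_factory=MoveConfig)
    init: str = "consensus"
    init_network: Optional[str] = None
    species: Optional[list[str]] = None  # required when run without data
    cache_likelihood: bool = False

    def resolved(self) -> tuple[int, int, int]:
        n = int(self.iterations)
        burn = n // 10 if self.burn_in is None else int(self.burn_in)
        if self.thin is None:
            thin = max(1, (n - burn) // 10_000)
        else:
            thin = int(self.thin)
        if not (n > burn >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        return n, burn, thin


@dataclass
class ChainRecord:
    iteration: int
    topology_key: str
    newick: str
    log_likelihood: float
    log_prior: float
    move: str
    accepted: bool

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior


class SampleChain:
    """Thinned post-burn-in samples plus per-move acceptance counts."""

    def __init__(self, records: list[ChainRecord],
                 proposed: Counter, accepted: Counter,
                 config: RunConfig):
        self.records = records
        self.proposed = proposed
        self.accepted = accepted
        self.config = config

    def __len__(self) -> int:
        return len(self.records)

    def topology_frequencies(self) -> Counter:
        return Counter(r.topology_key for r in self.records)

    def acceptance_rates(self) -> dict[str, float]:
        return {m: (self.accepted[m] / self.proposed[m]
                    if self.proposed[m] else math.nan) for m in MOVES}

    def map_record(self) -> ChainRecord:
        return max(self.records, key=lambda r: r.log_posterior)


# ----------------------------------------------------------------------
# initial states
# ----------------------------------------------------------------------

def random_tree(species: list[str], rng: np.random.Generator,
                delta: float = 1.0) -> PhyloNetwork:
    """A uniformly shaped random binary tree on ``species`` with
    Exponential(delta) branch lengths."""
    order = list(species)
    rng.shuffle(order)
    if len(order) < 2:
        raise ValueError("need at least two species")
    net = PhyloNetwork()
    root = net.add_node()
    net.add_edge(root, net.add_node(order[0]))
    net.add_edge(root, net.add_node(order[1]))
    for name in order[2:]:
        eids = sorted(net.edges)
        eid = eids[rng.integers(len(eids))]
        x = net.subdivide(eid, net.edges[eid].length / 2.0)
        net.add_edge(x, net.add_node(name))
    for e in net.edges.values():
        e.length = float(rng.exponential(1.0 / delta))
    return net


def greedy_consensus_tree(data: GeneTreeData, rng: np.random.Generator,
                          delta: float = 1.0) -> PhyloNetwork:
    """Greedy consensus of the input gene-tree multisets: clades ranked by
    their mean per-locus bootstrap support, added while compatible, then
    completed to a binary tree with random resolutions and Exp(delta)
    lengths.  Requires the trivial allele-to-species map (one individual
    per species); otherwise fall back to :func:`random_tree`."""
    alleles = data.alleles()
    tm = data.taxon_map or {}
    if any(tm.get(a, a) != a for a in alleles) or \
            len(set(tm.get(a, a) for a in alleles)) != len(alleles):
        return random_tree(data.species(), rng, delta)
    support: Counter = Counter()
    for pairs, n in data.locus_weights:
        for idx, k in pairs:
            for clade in data.topologies[idx].clades():
                if 1 < len(clade) < len(alleles):
                    support[clade] += k / n
    accepted: list[frozenset] = []
    for clade, _ in sorted(support.items(),
                           key=lambda kv: (-kv[1], len(kv[0]),
                                           sorted(kv[0]))):
        if all(clade <= c or c <= clade or not (clade & c)
               for c in accepted):
            accepted.append(clade)

    net = PhyloNetwork()

    def build(block: frozenset, parent: Optional[int]) -> None:
        inside = [c for c in accepted if c < block]
        maximal = [c for c in inside
                   if not any(c < d for d in inside)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        parts = maximal + [frozenset((x,)) for x in sorted(block - covered)]
        # random binary join of the parts
        while len(parts) > 2:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            merged = parts[i] | parts[j]
            parts = [p for k, p in enumerate(parts) if k not in (i, j)]
            parts.append(merged)
            accepted.append(merged)
        node = net.add_node()
        if parent is not None:
            net.add_edge(parent, node)
        for p in parts:
            if len(p) == 1:
                net.add_edge(node, net.add_node(next(iter(p))))
            else:
                build(p, node)

    build(frozenset(alleles), None)
    for e in net.edges.values():
        e.length = float(rng.exponential(1.0 / delta))
    return net


# ----------------------------------------------------------------------
# the chain
# ----------------------------------------------------------------------

def run_chain(data: Optional[GeneTreeData], cfg: RunConfig) -> SampleChain:
    """Run the Metropolis-Hastings chain and return the stored samples.

    ``data=None`` runs the chain against a likelihood identically equal to
    1 (prior sampling; ``cfg.species`` must then name the taxa), which is
    how the prior-recovery validations exercise the move kernel.
    """
    n_iter, burn_in, thin = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    prior = cfg.prior
    mcfg = cfg.moves
    if mcfg.max_reticulations is None:
        species = data.species() if data is not None else cfg.species
        if species is None:
            raise ValueError("species must be given when running "
                             "without data")
        mcfg = MoveConfig(**{**mcfg.__dict__,
                             "max_reticulations": max(1, len(species) - 1)})

    # initial state
    if cfg.init_network is not None:
        current = parse_network(cfg.init_network)
    elif cfg.init == "random" or data is None:
        species = data.species() if data is not None else cfg.species
        current = random_tree(list(species), rng, prior.delta)
    elif cfg.init == "consensus":
        current = greedy_consensus_tree(data, rng, prior.delta)
    else:
        raise ValueError(f"unknown init strategy {cfg.init!r}")
    bad = validate(current)
    if bad:
        raise ValueError(f"initial network invalid: {bad}")

    cache: dict[str, float] = {}

    def loglik(net: PhyloNetwork) -> float:
        if data is None:
            return 0.0
        if cfg.cache_likelihood:
            key = write_network(net)
            if key not in cache:
                if len(cache) > 4096:
                    cache.clear()
                cache[key] = data_loglikelihood(net, data)
            return cache[key]
        return data_loglikelihood(net, data)

    cur_lp = log_prior_network(current, prior) + log_prior_inheritance(current)
    if not math.isfinite(cur_lp):
        raise ValueError("initial network has zero prior; "
                         "start from a different network")
    cur_ll = loglik(current)
    if not math.isfinite(cur_ll):
        raise ValueError("initial network has zero likelihood; "
                         "start from a different network")
    cur_key = canonical_topology_key(current)

    records: list[ChainRecord] = []
    proposed: Counter = Counter()
    accepted_n: Counter = Counter()

    for it in range(1, n_iter + 1):
        kind, res = propose(current, mcfg, rng)
        proposed[kind] += 1
        accepted = False
        if res is not None:
            cand = res.network
            lp = log_prior_network(cand, prior) + log_prior_inheritance(cand)
            if math.isfinite(lp):
                ll = loglik(cand)
                logr = ((ll - cur_ll) + (lp - cur_lp)
                        + res.log_hastings + res.log_jacobian)
                if logr >= 0.0 or math.log(rng.random()) < logr:
                    accepted = True
                    current, cur_lp, cur_ll = cand, lp, ll
                    if kind in _TOPOLOGY_MOVES:
                        cur_key = canonical_topology_key(current)
        if accepted:
            accepted_n[kind] += 1
        if it > burn_in and (it - burn_in) % thin == 0:
            records.append(ChainRecord(
                it, cur_key, write_network(current),
                cur_ll, cur_lp, kind, accepted))
    return SampleChain(records, proposed, accepted_n, cfg)


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------

def credible_set(chain: SampleChain, level: float = 0.95
                 ) -> list[tuple[str, str, float]]:
    """The smallest set of sampled topologies whose cumulative posterior
    frequency reaches ``level``: a list of (topology key, representative
    extended Newick, frequency), sorted by descending frequency with ties
    broken lexicographically by key.  The representative is the
    highest-posterior sample of that topology."""
    if not chain.records:
        raise ValueError("empty chain")
    freqs = chain.topology_frequencies()
    total = sum(freqs.values())
    best: dict[str, ChainRecord] = {}
    for r in chain.records:
        b = best.get(r.topology_key)
        if b is None or r.log_posterior > b.log_posterior:
            best[r.topology_key] = r
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    cum = 0.0
    for key, count in ranked:
        frac = count / total
        out.append((key, best[key].newick, frac))
        cum += frac
        if cum >= level:
            break
    return out


def trace_summary(chain: SampleChain) -> dict[str, pd.DataFrame]:
    """Deterministic tabulation of the chain: a trace table (iteration,
    log-likelihood, log-prior, log-posterior, reticulation count implied by
    the move record) and a per-move acceptance table; both writable as
    delimited text for plotting."""
    trace = pd.DataFrame({
        "iteration": [r.iteration for r in chain.records],
        "log_likelihood": [r.log_likelihood for r in chain.records],
        "log_prior": [r.log_prior for r in chain.records],
        "log_posterior": [r.log_posterior for r in chain.records],
        "move": [r.move for r in chain.records],
        "accepted": [r.accepted for r in chain.records],
    })
    acc = pd.DataFrame({
        "move": list(MOVES),
        "proposed": [chain.proposed[m] for m in MOVES],
        "accepted": [chain.accepted[m] for m in MOVES],
    })
    acc["rate"] = [a / p if p else math.nan
                   for a, p in zip(acc["accepted"], acc["proposed"])]
    return {"trace": trace, "acceptance": acc}
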