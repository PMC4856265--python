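"""Prior distributions over phylogenetic networks and inheritance
probabilities.

The network prior factorizes as p(reticulation count) x p(branch lengths) x
p(topology):

* reticulation count ``m`` ~ Poisson(nu), divided by ``T_{n,m}``, the number
  of network topologies with ``n`` leaves and ``m`` reticulations (so each
  topology in a reticulation-count class carries equal weight);
* branch lengths i.i.d. Exponential(delta) per branch, in coalescent units;
* an optional Exponential(eta) penalty on a topology statistic coupled to the
  branch lengths; the statistic implemented is the "reticulation span" (the
  summed length of the two edges entering each reticulation node), and the
  term is off by default (eta = 0).

A candidate graph that violates the network definition (cycle, parallel
edge, extra root, degree or length violation — exactly what topology-changing
proposals can produce) receives prior probability zero, encoded as -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .network import PhyloNetwork, count_topologies, validate

__all__ = ["PriorConfig", "log_prior_network", "log_prior_inheritance",
           "reticulation_span"]


def reticulation_span(net: PhyloNetwork) -> float:
    """Total length of the reticulation edges (the two edges entering each
    reticulation node)."""
    return sum(e.length for e in net.reticulation_edges())


_STATISTICS = {"reticulation-span": reticulation_span}


@dataclass
class PriorConfig:
    """Hyperparameters of the (network, inheritance) prior.

    nu : Poisson mean for the number of reticulation nodes (> 0).
    delta : rate of the per-branch Exponential length prior (> 0).
    eta : rate of the optional topology penalty; 0 disables the term.
    topology_statistic : name of the penalized statistic (pluggable).
    t_nm_mode : how the topology count is evaluated.  "enumerate" uses the
        exact count (feasible for n <= 5, m <= 2); "constant-1" drops the
        factor, rescaling the relative weight of reticulation-count classes
        (and with it the complexity penalty the factor provides);
        "estimate" (the default) uses the exact count within the
        enumeration guard and extends it beyond with an insertion-count
        surrogate: each additional reticulation multiplies the class size
        by roughly (E+1) E / m placements (E the edge count), which keeps
        the strong growth of the topology classes -- and hence the
        shrinkage against spurious reticulations -- without exhaustive
        enumeration.
    """

    nu: float = 1.0
    delta: float = 1.0
    eta: float = 0.0
    topology_statistic: str = "reticulation-span"
    t_nm_mode: Literal["enumerate", "constant-1", "estimate"] = "estimate"

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.delta <= 0 or self.eta < 0:
            raise ValueError("need nu > 0, delta > 0, eta >= 0")
        if self.topology_statistic not in _STATISTICS:
            raise ValueError(
                f"unknown topology statistic {self.topology_statistic!r}")

    def log_t_nm(self, n: int, m: int) -> float:
        if self.t_nm_mode == "constant-1":
            return 0.0
        if self.t_nm_mode == "enumerate":
            return math.log(count_topologies(n, m))
        return log_t_nm_estimate(n, m)


def log_t_nm_estimate(n: int, m: int) -> float:
    """log T_{n,m}, exact where enumerable and extended beyond the guard by
    the insertion-count surrogate (see :class:`PriorConfig`), anchored at
    the largest exactly known class for that leaf count."""
    from .network import ENUM_MAX_LEAVES, ENUM_MAX_RETICULATIONS
    if n <= ENUM_MAX_LEAVES:
        m0 = min(m, ENUM_MAX_RETICULATIONS)
        base = math.log(count_topologies(n, m0))
    else:
        m0 = 0
        base = sum(math.log(k) for k in range(2 * n - 3, 0, -2))
    for j in range(m0 + 1, m + 1):
        edges = 2 * n - 2 + 3 * (j - 1)
        base += math.log((edges + 1) * edges / j)
    return base


def log_prior_network(net: PhyloNetwork, cfg: PriorConfig) -> float:
    """Log prior density of a candidate network; -inf iff invalid."""
    if validate(net):
        return -math.inf
    m = net.num_reticulations
    n = len(net.leaf_name)
    # Poisson(m; nu) / T_{n,m}
    lp = (m * math.log(cfg.nu) - cfg.nu - math.lgamma(m + 1)
          - cfg.log_t_nm(n, m))
    # i.i.d. Exp(delta) branch lengths
    log_delta = math.log(cfg.delta)
    for e in net.edges.values():
        lp += log_delta - cfg.delta * e.length
    # optional Exp(eta) topology penalty
    if cfg.eta > 0:
        s = _STATISTICS[cfg.topology_statistic](net)
        lp += math.log(cfg.eta) - cfg.eta * s
    return lp


def log_prior_inheritance(net_or_gammas) -> float:
    """Uniform prior on [0, 1] for every inheritance probability: 0 when all
    gamma values are in range, -inf otherwise.  Accepts a network (gamma
    values read off its reticulation edges) or a mapping node -> gamma; an
    empty map (a tree) has log prior 0."""
    if isinstance(net_or_gammas, PhyloNetwork):
        gammas = net_or_gammas.inheritance()
    elif hasattr(net_or_gammas, "gamma"):
        gammas = net_or_gammas.gamma
    else:
        gammas = dict(net_or_gammas)
    for g in gammas.values():
        if not 0.0 <= g <= 1.0:
            return -math.inf
    return 0.0
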