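"""Model/Results interface for Bayesian phylogenetic-network inference.

:class:`MSNCModel` bundles the gene-tree data with the prior and proposal
settings; :meth:`MSNCModel.fit` runs the reversible-jump sampler and returns
an :class:`MSNCResults` carrying the posterior sample, credible sets,
acceptance diagnostics and a text summary.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .likelihood import GeneTreeData
from .moves import MoveConfig
from .priors import PriorConfig
from .sampler import (RunConfig, SampleChain, credible_set, run_chain,
                      trace_summary)

__all__ = ["MSNCModel", "MSNCResults"]


class MSNCModel:
    """Posterior over (network, inheritance probabilities) given multi-locus
    gene-tree topology data under the multispecies network coalescent.

    Parameters
    ----------
    data
        The per-locus gene-tree multisets (``None`` runs against a unit
        likelihood, i.e. samples the prior; ``species`` must then be given).
    prior, moves
        Hyperparameters of the network/inheritance prior and the proposal
        kernel; defaults follow the package's documented choices.
    """

    def __init__(self, data: Optional[GeneTreeData],
                 prior: Optional[PriorConfig] = None,
                 moves: Optional[MoveConfig] = None,
                 species: Optional[Sequence[str]] = None):
        if data is None and species is None:
            raise ValueError("either data or species is required")
        self.data = data
        self.prior = prior or PriorConfig()
        self.moves = moves or MoveConfig()
        self.species = (list(species) if species is not None
                        else data.species())
        if data is not None:
            for sp in data.species():
                if sp not in self.species:
                    raise ValueError(f"species {sp!r} missing from network "
                                     "species set")

    @classmethod
    def from_newick_loci(cls, loci: Sequence[Sequence[str]],
                         taxon_map: Optional[Mapping[str, str]] = None,
                         **kwargs) -> "MSNCModel":
        """Build the model from per-locus lists of Newick strings."""
        return cls(GeneTreeData.from_newick_loci(loci, taxon_map), **kwargs)

    def fit(self, iterations: int = 5_000_000,
            burn_in: Optional[int] = None, thin: Optional[int] = None,
            seed: int = 0, init: str = "consensus",
            init_network: Optional[str] = None,
            cache_likelihood: bool = False) -> "MSNCResults":
        """Run the Metropolis-Hastings chain (reversible jump across
        reticulation counts) and return the posterior sample."""
        cfg = RunConfig(iterations=iterations, burn_in=burn_in, thin=thin,
                        seed=seed, prior=self.prior, moves=self.moves,
                        init=init, init_network=init_network,
                        species=self.species,
                        cache_likelihood=cache_likelihood)
        chain = run_chain(self.data, cfg)
        return MSNCResults(self, chain)


class MSNCResults:
    """Posterior sample of (network, inheritance) states with summaries."""

    def __init__(self, model: MSNCModel, chain: SampleChain):
        self.model = model
        self.chain = chain

    # -- point and set summaries ---------------------------------------
    @property
    def map_network(self) -> str:
        """Extended Newick of the highest-posterior sampled state."""
        return self.chain.map_record().newick

    def credible_set(self, level: float = 0.95,
                     flag_indistinguishable: float = 0.0
                     ) -> list[tuple[str, str, float]]:
        """The smallest set of topologies reaching cumulative posterior
        ``level``; see :func:`msnc.sampler.credible_set`.  With
        ``flag_indistinguishable`` > 0 an extra report column is not added;
        use :meth:`indistinguishable_keys` instead."""
        return credible_set(self.chain, level)

    def indistinguishable_keys(self, tol: float = 1e-6) -> list[set[str]]:
        """Groups of credible-set topologies whose best sampled
        log-likelihoods differ by less than ``tol`` (candidates for
        likelihood-indistinguishable alternatives)."""
        best: dict[str, float] = {}
        for r in self.chain.records:
            if r.topology_key not in best or \
                    r.log_likelihood > best[r.topology_key]:
                best[r.topology_key] = r.log_likelihood
        keys = [k for k, _, _ in credible_set(self.chain, 0.95)]
        groups: list[set[str]] = []
        for k in keys:
            placed = False
            for grp in groups:
                if any(abs(best[k] - best[j]) < tol for j in grp):
                    grp.add(k)
                    placed = True
                    break
            if not placed:
                groups.append({k})
        return [g for g in groups if len(g) > 1]

    def topology_posterior(self) -> pd.Series:
        freqs = self.chain.topology_frequencies()
        total = sum(freqs.values())
        return pd.Series({k: v / total for k, v in freqs.items()}
                         ).sort_values(ascending=False)

    # -- diagnostics ----------------------------------------------------
    def trace(self) -> pd.DataFrame:
        return trace_summary(self.chain)["trace"]

    def acceptance(self) -> pd.DataFrame:
        return trace_summary(self.chain)["acceptance"]

    def plot_trace(self, ax=None):
        """Log-posterior trace (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        tr = self.trace()
        ax.plot(tr["iteration"], tr["log_posterior"], lw=0.7)
        ax.set_xlabel("iteration")
        ax.set_ylabel("log posterior")
        return ax

    def summary(self, level: float = 0.95) -> str:
        """Human-readable report: sample size, credible set, acceptance."""
        cs = self.credible_set(level)
        lines = ["MSNC posterior summary",
                 "======================",
                 f"stored samples : {len(self.chain.records)}",
                 f"distinct topologies : "
                 f"{len(self.chain.topology_frequencies())}",
                 f"{int(level * 100)}% credible set "
                 f"({len(cs)} topolog{'y' if len(cs) == 1 else 'ies'}):"]
        for rank, (key, nwk, freq) in enumerate(cs, 1):
            lines.append(f"  {rank:2d}. p={freq:.4f}  {nwk}")
        lines.append("acceptance rates:")
        for _, row in self.acceptance().iterrows():
            if row["proposed"]:
                lines.append(f"  {row['move']:<20s} "
                             f"{row['accepted']:>7d}/{row['proposed']:<7d} "
                             f"({row['rate']:.3f})")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MSNCResults: {len(self.chain.records)} samples, "
                f"{len(self.chain.topology_frequencies())} topologies>")
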