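"""File I/O: gene-tree data sets, taxon maps, run configuration files,
manifests and report writing.

Gene-tree input dialect: plain Newick, one tree per line; lines beginning
``#locus`` separate loci within a file; alternatively each file is one
locus.  The taxon map is two-column text (allele, species), used when
several individuals are sampled per species.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .likelihood import GeneTreeData, GeneTreeTopology
from .sampler import SampleChain, credible_set, trace_summary

__all__ = ["load_taxon_map", "load_gene_tree_data", "load_config",
           "RunManifest", "write_samples_tsv", "write_credible_report",
           "write_trace_tsv"]


def load_taxon_map(path: Union[str, Path]) -> dict[str, str]:
    """Two-column text (allele species); '#' comments and blanks ignored."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'allele species', "
                             f"got {line!r}")
        out[parts[0]] = parts[1]
    return out


def _parse_tree_file(path: Path) -> list[list[str]]:
    """Split a gene-tree file into loci on '#locus' separator lines."""
    loci: list[list[str]] = []
    current: list[str] = []
    started = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.lower().startswith("#locus"):
            if started and current:
                loci.append(current)
            current = []
            started = True
            continue
        if line.startswith("#"):
            continue
        current.append(line)
    if current:
        loci.append(current)
    return loci


def load_gene_tree_data(paths: Sequence[Union[str, Path]],
                        taxon_map_path: Optional[Union[str, Path]] = None
                        ) -> GeneTreeData:
    """Assemble a :class:`GeneTreeData` from gene-tree files.

    A single file may hold several loci separated by ``#locus`` lines; with
    several files, each file contributes its loci in order.  When a taxon
    map is given, every allele label must appear in it (the offending
    allele is named otherwise); without one, alleles are species.
    """
    tmap = load_taxon_map(taxon_map_path) if taxon_map_path else None
    loci: list[list[GeneTreeTopology]] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"gene-tree file not found: {p}")
        for li, lines in enumerate(_parse_tree_file(p)):
            if not lines:
                raise ValueError(f"{p}: locus {li} is empty")
            loci.append([GeneTreeTopology.from_newick(s) for s in lines])
    if not loci:
        raise ValueError("no gene trees found in input")
    if tmap is not None:
        for locus in loci:
            for topo in locus:
                for allele in topo.taxa:
                    if allele not in tmap:
                        raise ValueError(
                            f"allele {allele!r} absent from the taxon map")
    return GeneTreeData(loci, tmap)


def load_config(path: Union[str, Path]) -> dict[str, str]:
    """key = value text config; '#' comments and blanks ignored."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


@dataclass
class RunManifest:
    """Reproducibility record written before sampling starts: resolved
    configuration, seed, input digests, software version, wall-clock
    stamps.  Every report references its manifest."""

    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""

    @staticmethod
    def digest(path: Union[str, Path]) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def stamp_start(self) -> None:
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")

    def stamp_end(self) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         default=str) + "\n")


def write_samples_tsv(chain: SampleChain, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("iteration\tlog_likelihood\tlog_prior\tmove\taccepted"
                 "\tnetwork\n")
        for r in chain.records:
            fh.write(f"{r.iteration}\t{r.log_likelihood:.6f}\t"
                     f"{r.log_prior:.6f}\t{r.move}\t{int(r.accepted)}\t"
                     f"{r.newick}\n")


def write_credible_report(chain: SampleChain, path: Union[str, Path],
                          level: float = 0.95) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tfrequency\tnetwork\n")
        for rank, (key, nwk, freq) in enumerate(
                credible_set(chain, level), 1):
            fh.write(f"{rank}\t{freq:.6f}\t{nwk}\n")


def write_trace_tsv(chain: SampleChain, path: Union[str, Path]) -> None:
    trace_summary(chain)["trace"].to_csv(path, sep="\t", index=False)
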