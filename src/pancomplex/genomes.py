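"""Core containers for orthogroup-labelled gene order.

A genome set is a collection of per-contig *chains*: ordered lists of
``(orthogroup_id, GeneRecord)`` pairs sorted by start coordinate.  Chains are
the only thing downstream graph construction looks at — coordinates are kept
solely to map graph nodes back to base pairs on a reference genome.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from dataclasses import dataclass

__all__ = ["GeneRecord", "OrthogroupAssignment", "GenomeSet"]

VALID_STRANDS = frozenset("+-")


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One protein-coding gene on one contig of one genome.

    Coordinates are 1-based inclusive; ``strand`` is ``'+'`` or ``'-'``.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )

    def flipped(self) -> "GeneRecord":
        """Return a copy with the strand toggled (coordinates unchanged)."""
        return dataclasses.replace(self, strand="-" if self.strand == "+" else "+")


class OrthogroupAssignment:
    """Mapping from gene id to orthogroup id.

    Every gene maps to at most one orthogroup; attempting to register a gene
    under two orthogroups raises ``ValueError``.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for gene, og in mapping.items():
                self.add(gene, og)

    def add(self, gene_id: str, orthogroup_id: str) -> None:
        prev = self._map.get(gene_id)
        if prev is not None and prev != orthogroup_id:
            raise ValueError(
                f"gene {gene_id!r} assigned to both {prev!r} and {orthogroup_id!r}"
            )
        self._map[gene_id] = orthogroup_id

    def get(self, gene_id: str) -> str | None:
        return self._map.get(gene_id)

    def __getitem__(self, gene_id: str) -> str:
        return self._map[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._map.items()

    @property
    def orthogroups(self) -> frozenset[str]:
        return frozenset(self._map.values())


ChainEntry = tuple[str, GeneRecord]  # (orthogroup_id, record)


class GenomeSet:
    """Ordered orthogroup chains per (genome, contig).

    ``chains`` maps ``(genome_id, contig_id)`` to a list of
    ``(orthogroup_id, GeneRecord)``.  ``flipped`` records which contigs were
    reversed by coalignment; a flipped chain is stored in reversed order with
    strands toggled.
    """

    def __init__(
        self,
        chains: dict[tuple[str, str], list[ChainEntry]],
        flipped: dict[tuple[str, str], bool] | None = None,
    ):
        self.chains = chains
        self.flipped = dict(flipped) if flipped else {key: False for key in chains}
        for key in chains:
            self.flipped.setdefault(key, False)
        # populated by io.build_genome_set; informational only
        self.report: dict[str, int] = {}

    # -- accessors ---------------------------------------------------------

    @property
    def genomes(self) -> list[str]:
        return sorted({g for g, _ in self.chains})

    def contigs(self, genome_id: str) -> list[str]:
        return sorted(c for g, c in self.chains if g == genome_id)

    def chain(self, genome_id: str, contig_id: str) -> list[ChainEntry]:
        return self.chains[(genome_id, contig_id)]

    def __contains__(self, genome_id: str) -> bool:
        return any(g == genome_id for g, _ in self.chains)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def adjacencies(self, genome_id: str) -> set[tuple[str, str]]:
        """Ordered orthogroup pairs adjacent on any contig of ``genome_id``."""
        pairs: set[tuple[str, str]] = set()
        for (g, _), chain in self.chains.items():
            if g != genome_id:
                continue
            for (u, _), (v, _) in zip(chain, chain[1:]):
                pairs.add((u, v))
        return pairs

    def subset(self, genome_ids: Iterable[str]) -> "GenomeSet":
        """Restrict the set to the given genomes (used by ``--subset``)."""
        keep = set(genome_ids)
        missing = keep - set(self.genomes)
        if missing:
            raise KeyError(f"genomes not in set: {sorted(missing)}")
        chains = {k: v for k, v in self.chains.items() if k[0] in keep}
        return GenomeSet(chains, {k: self.flipped[k] for k in chains})

    def with_chain_replaced(
        self, key: tuple[str, str], chain: list[ChainEntry], flipped: bool
    ) -> "GenomeSet":
        chains = dict(self.chains)
        chains[key] = chain
        flags = dict(self.flipped)
        flags[key] = flipped
        return GenomeSet(chains, flags)

    def __repr__(self) -> str:
        return (
            f"GenomeSet({len(self.genomes)} genomes, "
            f"{len(self.chains)} contigs, {self.n_genes} genes)"
        )
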