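"""Gene-neighborhood graph construction.

Nodes are orthogroups; a directed edge u→v exists when the corresponding
genes sit next to each other (u immediately followed by v) in at least one
genome, and its weight is the number of distinct genomes realizing that
adjacency.  Before building the graph, contigs are coaligned to a common
orientation and a paralog policy resolves orthogroups with multiple members
in one genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO

import networkx as nx
import numpy as np

from .genomes import ChainEntry, GenomeSet

log = logging.getLogger(__name__)

__all__ = [
    "GeneGraph",
    "ReferenceChain",
    "ParalogPolicy",
    "coalign_genomes",
    "apply_paralog_policy",
    "build_graph",
    "extract_reference_chain",
    "export_graph_sif",
]


@dataclass(frozen=True)
class ParalogPolicy:
    """How to treat orthogroups with ≥2 members in one genome.

    ``skip`` removes, per genome, every member of an orthogroup that is
    duplicated in that genome (the orthogroup stays in the graph for genomes
    carrying a single copy).  ``orthologize`` splits such orthogroups into
    context-specific nodes ``<og>_p<i>``: copies sharing the same
    (left-neighbor, right-neighbor) orthogroup context share a suffix.
    """

    mode: str = "skip"

    def __post_init__(self) -> None:
        if self.mode not in ("skip", "orthologize"):
            raise ValueError(f"unknown paralog policy {self.mode!r}")


class GeneGraph:
    """Directed multigenome adjacency graph over orthogroup nodes.

    Backed by a :class:`networkx.DiGraph`; each edge stores the set of
    supporting genomes, and its weight is the size of that set (a genome
    realizing the same adjacency on two contigs counts once).
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_adjacency(self, u: str, v: str, genome_id: str) -> None:
        data = self._g.get_edge_data(u, v)
        if data is None:
            self._g.add_edge(u, v, genomes={genome_id})
        else:
            data["genomes"].add(genome_id)

    @property
    def nx(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, node: str) -> bool:
        return node in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def weight(self, u: str, v: str) -> int:
        return len(self._g[u][v]["genomes"])

    def supporting_genomes(self, u: str, v: str) -> frozenset[str]:
        return frozenset(self._g[u][v]["genomes"])

    def edges(self):
        """Yield (source, target, weight)."""
        for u, v, data in self._g.edges(data=True):
            yield u, v, len(data["genomes"])

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges())

    def successor_map(self) -> dict[str, tuple[str, ...]]:
        """Out-neighbor lookup table for tight random-walk loops.

        Neighbor order is sorted so that seeded walks are reproducible
        regardless of insertion order.
        """
        return {n: tuple(sorted(self._g.successors(n))) for n in self._g.nodes}


@dataclass
class ReferenceChain:
    """The ordered node sequence of one reference genome contig.

    ``coords``/``ends`` give the start/end base pair of each node's
    representative gene; ``position`` maps node id to 0-based chain index.
    """

    genome_id: str
    contig_id: str
    nodes: list[str]
    coords: np.ndarray
    ends: np.ndarray
    products: list[str] = field(default_factory=list)
    position: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.position = {node: i for i, node in enumerate(self.nodes)}
        if len(self.position) != len(self.nodes):
            # should not happen after the skip policy; keep first occurrence
            log.warning(
                "reference chain %s/%s has repeated nodes; keeping first positions",
                self.genome_id,
                self.contig_id,
            )
            self.position = {}
            for i, node in enumerate(self.nodes):
                self.position.setdefault(node, i)

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# coalignment
# ---------------------------------------------------------------------------


def coalign_genomes(
    gs: GenomeSet, reference_genome: str, enabled: bool = True
) -> GenomeSet:
    """Orient every contig consistently with the reference genome.

    A non-reference contig is flipped (chain reversed, strands toggled) iff
    flipping strictly increases the number of ordered orthogroup adjacencies
    it shares with the reference; ties keep the original orientation.  The
    reference is never flipped.  With ``enabled=False`` the set is returned
    unchanged (the step is optional because it scales with contig count).
    """
    if reference_genome not in gs:
        raise KeyError(f"reference genome {reference_genome!r} not in set")
    if not enabled:
        return gs
    ref_adj = gs.adjacencies(reference_genome)
    chains: dict[tuple[str, str], list[ChainEntry]] = {}
    flags: dict[tuple[str, str], bool] = {}
    n_flipped = 0
    for key, chain in gs.chains.items():
        genome_id, _ = key
        if genome_id == reference_genome:
            chains[key] = chain
            flags[key] = gs.flipped.get(key, False)
            continue
        forward = 0
        backward = 0
        for (u, _), (v, _) in zip(chain, chain[1:]):
            if (u, v) in ref_adj:
                forward += 1
            if (v, u) in ref_adj:
                backward += 1
        if backward > forward:
            chains[key] = [(og, rec.flipped()) for og, rec in reversed(chain)]
            flags[key] = not gs.flipped.get(key, False)
            n_flipped += 1
        else:
            chains[key] = chain
            flags[key] = gs.flipped.get(key, False)
    if n_flipped:
        log.info("coalignment flipped %d contigs", n_flipped)
    return GenomeSet(chains, flags)


# ---------------------------------------------------------------------------
# paralog policies
# ---------------------------------------------------------------------------


def apply_paralog_policy(gs: GenomeSet, policy: ParalogPolicy | str) -> GenomeSet:
    if isinstance(policy, str):
        policy = ParalogPolicy(policy)
    if policy.mode == "skip":
        return _apply_skip(gs)
    return _apply_orthologize(gs)


def _genome_og_counts(gs: GenomeSet) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    for (genome_id, _), chain in gs.chains.items():
        per = counts.setdefault(genome_id, {})
        for og, _ in chain:
            per[og] = per.get(og, 0) + 1
    return counts


def _apply_skip(gs: GenomeSet) -> GenomeSet:
    counts = _genome_og_counts(gs)
    chains = {}
    removed = 0
    for key, chain in gs.chains.items():
        genome_id, _ = key
        per = counts[genome_id]
        kept = [(og, rec) for og, rec in chain if per[og] == 1]
        removed += len(chain) - len(kept)
        chains[key] = kept
    if removed:
        log.info("paralog policy 'skip' removed %d gene copies", removed)
    out = GenomeSet(chains, gs.flipped)
    out.report = dict(gs.report, n_paralog_removed=removed)
    return out


def _apply_orthologize(gs: GenomeSet) -> GenomeSet:
    """Split duplicated orthogroups into context-specific nodes.

    An orthogroup duplicated in any genome is renamed, for *all* its copies
    across the set, to ``<og>_p<i>`` where the suffix indexes the copy's
    (left, right) neighbor-orthogroup context.  Suffixes follow first
    encounter over (genome, contig) keys in sorted order, so the relabelling
    is deterministic.
    """
    counts = _genome_og_counts(gs)
    duplicated = {
        og for per in counts.values() for og, n in per.items() if n >= 2
    }
    context_suffix: dict[str, dict[tuple[str | None, str | None], int]] = {
        og: {} for og in duplicated
    }
    chains = {}
    for key in sorted(gs.chains):
        chain = gs.chains[key]
        new_chain: list[ChainEntry] = []
        for i, (og, rec) in enumerate(chain):
            if og not in duplicated:
                new_chain.append((og, rec))
                continue
            left = chain[i - 1][0] if i > 0 else None
            right = chain[i + 1][0] if i < len(chain) - 1 else None
            table = context_suffix[og]
            suffix = table.setdefault((left, right), len(table) + 1)
            new_chain.append((f"{og}_p{suffix}", rec))
        chains[key] = new_chain
    out = GenomeSet(chains, gs.flipped)
    out.report = dict(gs.report, n_orthologized=len(duplicated))
    return out


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_graph(gs: GenomeSet) -> GeneGraph:
    """Build the directed weighted adjacency graph from post-policy chains."""
    if not gs.chains or gs.n_genes == 0:
        raise ValueError("cannot build a graph from an empty genome set")
    graph = GeneGraph()
    for key in sorted(gs.chains):
        genome_id, _ = key
        chain = gs.chains[key]
        for og, _ in chain:
            graph.add_node(og)
        for (u, _), (v, _) in zip(chain, chain[1:]):
            graph.add_adjacency(u, v, genome_id)
    return graph


def extract_reference_chain(
    graph: GeneGraph,
    gs: GenomeSet,
    genome_id: str,
    contig_id: str | None = None,
    min_informative: int = 42,
) -> ReferenceChain:
    """Extract one contig of one genome as the reference chain.

    ``contig_id`` may be omitted when the genome has a single contig.  Chains
    shorter than ``min_informative`` (2·default window + 2) trigger a warning:
    complexity on them is poorly defined.
    """
    if genome_id not in gs:
        raise KeyError(f"unknown genome {genome_id!r}")
    if contig_id is None:
        contigs = gs.contigs(genome_id)
        if len(contigs) != 1:
            raise ValueError(
                f"genome {genome_id!r} has {len(contigs)} contigs; specify one"
            )
        contig_id = contigs[0]
    if (genome_id, contig_id) not in gs.chains:
        raise KeyError(f"unknown contig {contig_id!r} for genome {genome_id!r}")
    chain = gs.chains[(genome_id, contig_id)]
    if len(chain) < min_informative:
        log.warning(
            "reference chain %s/%s has only %d nodes; complexity may be uninformative",
            genome_id,
            contig_id,
            len(chain),
        )
    for og, _ in chain:
        if og not in graph:
            raise ValueError(f"reference node {og!r} missing from graph")
    return ReferenceChain(
        genome_id=genome_id,
        contig_id=contig_id,
        nodes=[og for og, _ in chain],
        coords=np.array([rec.start for _, rec in chain], dtype=np.int64),
        ends=np.array([rec.end for _, rec in chain], dtype=np.int64),
        products=[rec.product for _, rec in chain],
    )


def export_graph_sif(
    graph: GeneGraph, sif_stream: IO[str], weights_stream: IO[str] | None = None
) -> None:
    """Write the graph as SIF (``u<TAB>adj<TAB>v``) plus a weight sidecar."""
    edges = sorted(graph.edges())
    for u, v, _ in edges:
        sif_stream.write(f"{u}\tadj\t{v}\n")
    if weights_stream is not None:
        weights_stream.write("source\ttarget\tweight\n")
        for u, v, w in edges:
            weights_stream.write(f"{u}\t{v}\t{w}\n")
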