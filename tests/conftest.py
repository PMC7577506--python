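"""Shared fixture builders: tiny genome sets specified as orthogroup lists."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import pytest

from pancomplex.genomes import GeneRecord, GenomeSet
from pancomplex.graph import (
    apply_paralog_policy,
    build_graph,
    coalign_genomes,
    extract_reference_chain,
)

SPACING = 1000
SPAN = 900


def make_genome_set(spec: dict) -> GenomeSet:
    """Build a GenomeSet from ``{genome: [og, ...]}`` or
    ``{genome: {contig: [og, ...]}}``; genes get synthetic 1-based
    coordinates 1..900, 1001..1900, ... on each contig."""
    chains = {}
    for genome, value in spec.items():
        per_contig = value if isinstance(value, dict) else {"c1": value}
        for contig, ogs in per_contig.items():
            chain = []
            for i, og in enumerate(ogs):
                start = i * SPACING + 1
                rec = GeneRecord(
                    gene_id=f"{genome}.{contig}.{i}",
                    genome_id=genome,
                    contig_id=contig,
                    start=start,
                    end=start + SPAN - 1,
                    strand="+",
                    product=f"{og} protein",
                )
                chain.append((og, rec))
            chains[(genome, contig)] = chain
    return GenomeSet(chains)


def pipeline(spec: dict, reference: str, contig: str = "c1", *,
             coalign: bool = False, policy: str = "skip"):
    """GenomeSet → (post-policy set, graph, reference chain)."""
    gs = make_genome_set(spec)
    gs = coalign_genomes(gs, reference, enabled=coalign)
    gs = apply_paralog_policy(gs, policy)
    graph = build_graph(gs)
    chain = extract_reference_chain(graph, gs, reference, contig)
    return gs, graph, chain


@pytest.fixture
def single_bypass():
    """Reference A-X-C plus one genome with X replaced by B1."""
    spec = {"ref": ["A", "X", "C"], "alt": ["A", "B1", "C"]}
    return pipeline(spec, "ref")
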