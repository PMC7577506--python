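"""Region subgraph extraction for visualization.

Given a base-pair window on the reference genome, the subgraph contains the
reference chain segment through that window plus, from every other genome,
the deviating runs (maximal stretches of non-region nodes flanked by region
nodes).  Runs longer than ``depth`` are cropped to their first and last
``tails`` nodes, left dangling and flagged, so that very long insertions do
not swamp the picture.  Edges below ``minimal_edge_weight`` are dropped.
Exports: SIF (plus a weight sidecar) and Cytoscape.js-style JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO

from .genomes import GenomeSet
from .graph import GeneGraph, ReferenceChain

__all__ = ["SubgraphParams", "Subgraph", "generate_subgraph", "export_sif", "export_json"]

MAX_REGION_BP = 100_000  # keep visualizations tractable


@dataclass(frozen=True)
class SubgraphParams:
    start_bp: int
    end_bp: int
    depth: int = 20
    tails: int = 5
    minimal_edge_weight: int = 1

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if self.end_bp - self.start_bp > MAX_REGION_BP:
            raise ValueError(
                f"region spans {self.end_bp - self.start_bp} bp; "
                f"must not exceed {MAX_REGION_BP} bp"
            )
        if self.tails >= self.depth:
            raise ValueError("tails must be < depth")
        if self.minimal_edge_weight < 1:
            raise ValueError("minimal_edge_weight must be >= 1")


@dataclass
class Subgraph:
    """Node/edge payload of one extracted region."""

    nodes: dict[str, dict] = field(default_factory=dict)
    # (source, target) -> weight
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def add_node(
        self, node: str, *, on_reference: bool, cropped_tail: bool = False,
        product: str = ""
    ) -> None:
        entry = self.nodes.setdefault(
            node, {"on_reference": on_reference, "cropped_tail": cropped_tail,
                   "product": product}
        )
        entry["on_reference"] = entry["on_reference"] or on_reference
        entry["cropped_tail"] = entry["cropped_tail"] or cropped_tail
        if product and not entry["product"]:
            entry["product"] = product

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def generate_subgraph(
    graph: GeneGraph,
    ref_chain: ReferenceChain,
    gs: GenomeSet,
    params: SubgraphParams,
) -> Subgraph:
    """Extract the cropped subgraph for a reference region.

    Region membership is by gene start coordinate in
    ``[start_bp, end_bp]``.  Deviating runs from other genomes are collected
    per contig; runs touching a contig end next to a region node are kept as
    one-sided fragments (draft-genome boundaries would otherwise silently
    hide context).
    """
    idx = [
        i
        for i in range(len(ref_chain))
        if params.start_bp <= int(ref_chain.coords[i]) <= params.end_bp
    ]
    if not idx:
        raise ValueError("region contains no reference genes")
    if len(idx) < 2:
        raise ValueError("region must contain at least 2 reference nodes")
    region_nodes = [ref_chain.nodes[i] for i in idx]
    region_set = set(region_nodes)
    backbone = set(ref_chain.nodes)

    sub = Subgraph()
    for i in idx:
        sub.add_node(
            ref_chain.nodes[i],
            on_reference=True,
            product=ref_chain.products[i] if ref_chain.products else "",
        )
    candidate_edges: set[tuple[str, str]] = set()
    for u, v in zip(region_nodes, region_nodes[1:]):
        if graph.nx.has_edge(u, v):
            candidate_edges.add((u, v))

    for key in sorted(gs.chains):
        genome_id, _ = key
        if genome_id == ref_chain.genome_id:
            continue
        chain = [og for og, _ in gs.chains[key]]
        products = {og: rec.product for og, rec in gs.chains[key]}
        in_region = [og in region_set for og in chain]
        i = 0
        n = len(chain)
        while i < n:
            if in_region[i]:
                # direct adjacency between two region nodes in this genome
                if i + 1 < n and in_region[i + 1]:
                    candidate_edges.add((chain[i], chain[i + 1]))
                i += 1
                continue
            j = i
            while j + 1 < n and not in_region[j + 1]:
                j += 1
            left_anchored = i > 0 and in_region[i - 1]
            right_anchored = j + 1 < n and in_region[j + 1]
            if left_anchored or right_anchored:
                lo, hi = i, j
                # a run that exits through a contig end is truncated where the
                # genome rejoins the reference backbone outside the region:
                # from there on it is ordinary flanking sequence, not deviation
                if left_anchored and not right_anchored:
                    hi = i - 1
                    for pos in range(i, j + 1):
                        if chain[pos] in backbone:
                            break
                        hi = pos
                elif right_anchored and not left_anchored:
                    lo = j + 1
                    for pos in range(j, i - 1, -1):
                        if chain[pos] in backbone:
                            break
                        lo = pos
                if lo <= hi:
                    _add_run(
                        sub,
                        candidate_edges,
                        chain,
                        products,
                        lo,
                        hi,
                        left_anchored and lo == i,
                        right_anchored and hi == j,
                        params,
                    )
            i = j + 1

    for u, v in candidate_edges:
        if not graph.nx.has_edge(u, v):
            continue
        w = graph.weight(u, v)
        if w < params.minimal_edge_weight:
            continue
        if u in sub.nodes and v in sub.nodes:
            sub.edges[(u, v)] = w

    # prune non-reference nodes disconnected by the weight filter
    touched = {n for edge in sub.edges for n in edge}
    for node in list(sub.nodes):
        if node not in touched and not sub.nodes[node]["on_reference"]:
            del sub.nodes[node]
    return sub


def _add_run(
    sub: Subgraph,
    candidate_edges: set[tuple[str, str]],
    chain: list[str],
    products: dict[str, str],
    i: int,
    j: int,
    left_anchored: bool,
    right_anchored: bool,
    params: SubgraphParams,
) -> None:
    run = chain[i : j + 1]
    if len(run) <= params.depth:
        kept_idx = list(range(len(run)))
        cropped: set[int] = set()
    else:
        head = list(range(params.tails))
        tail = list(range(len(run) - params.tails, len(run)))
        kept_idx = head + tail
        cropped = {head[-1], tail[0]}
    kept = set(kept_idx)
    for pos in kept_idx:
        sub.add_node(
            run[pos],
            on_reference=False,
            cropped_tail=pos in cropped,
            product=products.get(run[pos], ""),
        )
    for pos in kept_idx:
        if pos + 1 in kept:
            candidate_edges.add((run[pos], run[pos + 1]))
    if left_anchored:
        candidate_edges.add((chain[i - 1], run[0]))
    if right_anchored:
        candidate_edges.add((run[-1], chain[j + 1]))


def export_sif(
    sub: Subgraph, stream: IO[str], weights_stream: IO[str] | None = None
) -> None:
    """SIF: one ``source<TAB>adj<TAB>target`` line per edge; weights go to a
    sidecar TSV when a second stream is given."""
    edges = sorted(sub.edges.items())
    for (u, v), _ in edges:
        stream.write(f"{u}\tadj\t{v}\n")
    if weights_stream is not None:
        weights_stream.write("source\ttarget\tweight\n")
        for (u, v), w in edges:
            weights_stream.write(f"{u}\t{v}\t{w}\n")


def export_json(sub: Subgraph, stream: IO[str]) -> None:
    """Cytoscape.js-style element JSON."""
    payload = {
        "elements": {
            "nodes": [
                {
                    "data": {
                        "id": node,
                        "product": attrs["product"],
                        "on_reference": attrs["on_reference"],
                        "cropped_tail": attrs["cropped_tail"],
                    }
                }
                for node, attrs in sorted(sub.nodes.items())
            ],
            "edges": [
                {"data": {"source": u, "target": v, "weight": w}}
                for (u, v), w in sorted(sub.edges.items())
            ],
        }
    }
    json.dump(payload, stream, indent=1)
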