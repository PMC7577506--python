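"""Model/Results facade over the pipeline.

:class:`GenomeComplexity` plays the role of a model object: it is
constructed from a genome set plus the choices that fix the graph
(reference genome, coalignment, paralog policy), and :meth:`fit` runs the
Monte-Carlo complexity estimation, returning a
:class:`GenomeComplexityResults` that carries the profiles, hotspot
diagnostics, a text ``summary()`` and export/plot helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as io_formats
from .complexity import (
    ComplexityParams,
    ComplexityProfile,
    HotspotResult,
    compute_complexity,
    detect_hotspots,
)
from .genomes import GenomeSet
from .graph import (
    GeneGraph,
    ParalogPolicy,
    ReferenceChain,
    apply_paralog_policy,
    build_graph,
    coalign_genomes,
    extract_reference_chain,
)
from .subgraph import Subgraph, SubgraphParams, generate_subgraph

__all__ = ["GenomeComplexity", "GenomeComplexityResults"]


class GenomeComplexity:
    """Gene-neighborhood graph model of a genome set.

    Parameters
    ----------
    genome_set
        Orthogroup-labelled gene chains for ≥ 2 genomes.
    reference
        Genome id against which complexity is computed.
    contig
        Restrict to one reference contig; by default every contig of the
        reference gets its own profile.
    coalign
        Orient all contigs consistently with the reference before building
        the graph (recommended; skippable for very fragmented inputs).
    paralog_policy
        'skip' (default) or 'orthologize'.
    """

    def __init__(
        self,
        genome_set: GenomeSet,
        reference: str,
        contig: str | None = None,
        coalign: bool = True,
        paralog_policy: str | ParalogPolicy = "skip",
    ):
        if reference not in genome_set:
            raise KeyError(f"reference genome {reference!r} not in set")
        self.reference = reference
        self.contig = contig
        self.coalign = coalign
        self.paralog_policy = (
            paralog_policy
            if isinstance(paralog_policy, ParalogPolicy)
            else ParalogPolicy(paralog_policy)
        )
        aligned = coalign_genomes(genome_set, reference, enabled=coalign)
        self.genome_set: GenomeSet = apply_paralog_policy(aligned, self.paralog_policy)
        self.graph: GeneGraph = build_graph(self.genome_set)
        contigs = [contig] if contig is not None else self.genome_set.contigs(reference)
        self.chains: dict[str, ReferenceChain] = {
            c: extract_reference_chain(self.graph, self.genome_set, reference, c)
            for c in contigs
        }

    @classmethod
    def from_files(
        cls,
        orthogroups: str,
        annotations: str,
        *,
        reference: str,
        orthogroup_dialect: str = "orthofinder_tsv",
        annotation_dialect: str = "gene_table",
        subset: list[str] | None = None,
        **kwargs,
    ) -> "GenomeComplexity":
        """Build the model straight from an orthogroup table and a gene table."""
        with open(orthogroups) as fh:
            assignment = io_formats.parse_orthogroup_table(fh, orthogroup_dialect)
        with open(annotations) as fh:
            records = io_formats.parse_gene_annotations(fh, annotation_dialect)
        gs = io_formats.build_genome_set(assignment, records)
        if subset:
            gs = gs.subset(set(subset) | {reference})
        return cls(gs, reference=reference, **kwargs)

    def fit(
        self,
        window: int = 20,
        iterations: int = 500,
        seed: int = 0,
        method: str = "sampled",
    ) -> "GenomeComplexityResults":
        """Estimate the complexity profile of every reference contig.

        ``method='exhaustive'`` replaces the random walker by full path
        enumeration (only viable on small graphs; used for validation).
        """
        params = ComplexityParams(window=window, iterations=iterations, rng_seed=seed)
        terminate = {
            node for chain in self.chains.values() for node in chain.nodes
        }
        profiles = {
            contig: compute_complexity(
                self.graph, chain, params, method=method, terminate_on=terminate
            )
            for contig, chain in self.chains.items()
        }
        return GenomeComplexityResults(self, profiles, params)


@dataclass
class GenomeComplexityResults:
    """Fitted complexity profiles plus diagnostics."""

    model: GenomeComplexity
    profiles: dict[str, ComplexityProfile]
    params: ComplexityParams

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([p.values for p in self.profiles.values()])

    def profile_frame(self) -> pd.DataFrame:
        rows = []
        for contig, profile in self.profiles.items():
            chain = profile.chain
            for i, value in enumerate(profile.values):
                rows.append(
                    {
                        "contig": contig,
                        "node": chain.nodes[i],
                        "start_bp": int(chain.coords[i]),
                        "end_bp": int(chain.ends[i]),
                        "complexity": float(value),
                    }
                )
        return pd.DataFrame(rows)

    def hotspots(self, k: float = 1.5) -> dict[str, HotspotResult]:
        return {
            contig: detect_hotspots(profile, k=k)
            for contig, profile in self.profiles.items()
        }

    def hotspot_frame(self, k: float = 1.5) -> pd.DataFrame:
        rows = []
        for contig, result in self.hotspots(k=k).items():
            for region in result.regions:
                rows.append(
                    {
                        "contig": contig,
                        "start_bp": region.start_bp,
                        "end_bp": region.end_bp,
                        "n_genes": region.n_genes,
                        "max_complexity": region.max_complexity,
                    }
                )
        return pd.DataFrame(
            rows, columns=["contig", "start_bp", "end_bp", "n_genes", "max_complexity"]
        )

    def save_track(self, path: str, contig: str | None = None) -> None:
        profile = self._one_profile(contig)
        with open(path, "w") as fh:
            io_formats.write_track(profile.to_pairs(), fh)

    def subgraph(
        self,
        start_bp: int,
        end_bp: int,
        contig: str | None = None,
        depth: int = 20,
        tails: int = 5,
        minimal_edge_weight: int = 1,
    ) -> Subgraph:
        profile = self._one_profile(contig)
        params = SubgraphParams(
            start_bp=start_bp,
            end_bp=end_bp,
            depth=depth,
            tails=tails,
            minimal_edge_weight=minimal_edge_weight,
        )
        return generate_subgraph(
            self.model.graph, profile.chain, self.model.genome_set, params
        )

    def plot(self, contig: str | None = None, ax=None, k: float | None = 1.5):
        """Complexity along the reference, with hotspot genes marked."""
        import matplotlib.pyplot as plt

        profile = self._one_profile(contig)
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        coords = profile.chain.coords
        ax.plot(coords, profile.values, lw=0.8, color="tab:blue")
        if k is not None:
            result = detect_hotspots(profile, k=k)
            for region in result.regions:
                ax.axvspan(region.start_bp, region.end_bp, color="tab:orange", alpha=0.3)
            ax.axhline(result.threshold, color="tab:red", ls="--", lw=0.8)
        ax.set_xlabel("reference position (bp)")
        ax.set_ylabel("complexity")
        ax.set_title(f"{profile.chain.genome_id}/{profile.chain.contig_id}")
        return ax

    def summary(self, k: float = 1.5) -> str:
        model = self.model
        lines = [
            "Genome complexity estimation",
            "=" * 60,
            f"genomes:            {len(model.genome_set.genomes)}",
            f"graph nodes:        {model.graph.n_nodes}",
            f"graph edges:        {model.graph.n_edges}",
            f"reference:          {model.reference}",
            f"paralog policy:     {model.paralog_policy.mode}",
            f"coalign:            {model.coalign}",
            f"window:             {self.params.window}",
            f"iterations:         {self.params.iterations}",
            f"seed:               {self.params.rng_seed}",
            "-" * 60,
        ]
        for contig, profile in self.profiles.items():
            result = detect_hotspots(profile, k=k)
            values = profile.values
            lines += [
                f"contig {contig}: {len(values)} nodes",
                f"  complexity mean/max:   {values.mean():.4f} / {values.max():.4f}",
                f"  hotspot threshold (k={k}): {result.threshold:.4f}",
                f"  hotspot regions:       {len(result.regions)}",
            ]
        return "\n".join(lines)

    def _one_profile(self, contig: str | None) -> ComplexityProfile:
        if contig is None:
            if len(self.profiles) != 1:
                raise ValueError(
                    f"results cover {len(self.profiles)} contigs; specify one"
                )
            return next(iter(self.profiles.values()))
        return self.profiles[contig]
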