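"""Readers and writers for the text formats the pipeline speaks.

Supported inputs: OrthoFinder ``Orthogroups.tsv``, a plain two-column
gene↔orthogroup TSV, GFF3 (CDS features only) and a flat seven-column gene
table.  Outputs: ``<position>\\t<value>`` numeric tracks, a hotspot TSV and an
optional minimal SQLite database.
"""

from __future__ import annotations

import logging
import sqlite3
from collections.abc import Iterable, Sequence
from typing import IO, TYPE_CHECKING
from urllib.parse import unquote

from .genomes import GeneRecord, GenomeSet, OrthogroupAssignment

if TYPE_CHECKING:  # pragma: no cover
    from .complexity import ComplexityProfile, HotspotRegion
    from .graph import GeneGraph

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "parse_orthogroup_table",
    "parse_gene_annotations",
    "build_genome_set",
    "write_track",
    "read_track",
    "write_hotspots",
    "write_genome_set_tables",
    "save_sqlite",
]

GENE_TABLE_COLUMNS = (
    "gene_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "product",
)


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# orthogroup tables
# ---------------------------------------------------------------------------


def parse_orthogroup_table(
    stream: Iterable[str], dialect: str = "orthofinder_tsv"
) -> OrthogroupAssignment:
    """Parse a gene→orthogroup assignment.

    ``orthofinder_tsv``: first column is the orthogroup id, remaining columns
    hold comma-separated gene ids (one column per genome); a leading header
    row starting with ``Orthogroup`` is skipped.  ``two_column``:
    ``gene_id<TAB>orthogroup_id`` per line.
    """
    if dialect not in ("orthofinder_tsv", "two_column"):
        raise ValueError(f"unknown orthogroup table dialect {dialect!r}")
    assignment = OrthogroupAssignment()
    n_lines = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if dialect == "two_column":
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"expected 'gene_id<TAB>orthogroup_id', got {line!r}", lineno
                )
            gene, og = fields
            _assign(assignment, gene.strip(), og.strip(), lineno)
        else:
            if lineno == 1 and fields[0].strip().lower() == "orthogroup":
                continue
            if len(fields) < 2:
                raise ParseError(
                    f"expected orthogroup id plus at least one gene column, got {line!r}",
                    lineno,
                )
            og = fields[0].strip()
            if not og:
                raise ParseError("empty orthogroup id", lineno)
            for cell in fields[1:]:
                for gene in cell.split(","):
                    gene = gene.strip()
                    if gene:
                        _assign(assignment, gene, og, lineno)
        n_lines += 1
    if len(assignment) == 0:
        raise ParseError("orthogroup table contains no assignments")
    log.info("parsed %d gene assignments across %d orthogroups",
             len(assignment), len(assignment.orthogroups))
    return assignment


def _assign(assignment: OrthogroupAssignment, gene: str, og: str, lineno: int) -> None:
    try:
        assignment.add(gene, og)
    except ValueError as exc:
        raise ParseError(str(exc), lineno) from exc


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------


def parse_gene_annotations(
    stream: Iterable[str],
    dialect: str = "gene_table",
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Parse gene annotations into sorted :class:`GeneRecord` lists.

    ``gff3`` reads CDS features only, taking the gene id from the ``ID``
    attribute and the product from the ``product`` attribute; ``genome_id``
    must then be supplied (GFF3 files carry no genome identifier).
    ``gene_table`` is a flat tab-separated layout::

        gene_id  genome_id  contig_id  start  end  strand  product

    Records are returned sorted by (genome, contig, start, end, gene_id).
    """
    if dialect == "gff3":
        records = _parse_gff3(stream, genome_id)
    elif dialect == "gene_table":
        records = _parse_gene_table(stream)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    records.sort(key=lambda r: (r.genome_id, r.contig_id, r.start, r.end, r.gene_id))
    return records


def _parse_gff3(stream: Iterable[str], genome_id: str | None) -> list[GeneRecord]:
    if genome_id is None:
        raise ValueError("genome_id is required for the gff3 dialect")
    records = []
    skipped = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            if line.startswith("##FASTA"):
                break
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"expected 9 GFF3 columns, got {len(fields)}", lineno)
        contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype != "CDS":
            skipped += 1
            continue
        attr_map = {}
        for item in attrs.split(";"):
            if "=" in item:
                key, _, value = item.partition("=")
                attr_map[key.strip()] = unquote(value.strip())
        gene_id = attr_map.get("ID")
        if not gene_id:
            raise ParseError("CDS feature lacks an ID attribute", lineno)
        records.append(
            _make_record(
                gene_id,
                genome_id,
                contig,
                start,
                end,
                strand,
                attr_map.get("product", ""),
                lineno,
            )
        )
    if skipped:
        log.info("skipped %d non-CDS GFF3 features", skipped)
    return records


def _parse_gene_table(stream: Iterable[str]) -> list[GeneRecord]:
    records = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "gene_id":
            continue
        if len(fields) < 6:
            raise ParseError(
                f"expected {len(GENE_TABLE_COLUMNS)} tab-separated columns, "
                f"got {len(fields)}",
                lineno,
            )
        gene_id, genome, contig, start, end, strand = fields[:6]
        product = fields[6] if len(fields) > 6 else ""
        records.append(
            _make_record(gene_id, genome, contig, start, end, strand, product, lineno)
        )
    return records


def _make_record(
    gene_id: str,
    genome: str,
    contig: str,
    start: str,
    end: str,
    strand: str,
    product: str,
    lineno: int,
) -> GeneRecord:
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ParseError(f"non-integer coordinate for gene {gene_id!r}", lineno) from exc
    try:
        return GeneRecord(gene_id, genome, contig, start_i, end_i, strand, product)
    except ValueError as exc:
        raise ParseError(str(exc), lineno) from exc


# ---------------------------------------------------------------------------
# genome set assembly
# ---------------------------------------------------------------------------


def build_genome_set(
    assignment: OrthogroupAssignment, records: Sequence[GeneRecord]
) -> GenomeSet:
    """Assemble per-contig orthogroup chains from annotated genes.

    Genes without an orthogroup assignment are omitted from the chains (their
    neighbours become adjacent); the number dropped is logged and recorded in
    ``GenomeSet.report``.  Requires at least two genomes.
    """
    chains: dict[tuple[str, str], list[tuple[str, GeneRecord]]] = {}
    seen_positions: set[tuple[str, str, int]] = set()
    dropped = 0
    ordered = sorted(
        records, key=lambda r: (r.genome_id, r.contig_id, r.start, r.end, r.gene_id)
    )
    for rec in ordered:
        pos_key = (rec.genome_id, rec.contig_id, rec.start)
        if pos_key in seen_positions:
            raise ValueError(
                f"duplicate gene start {rec.start} on {rec.genome_id}/{rec.contig_id}"
            )
        seen_positions.add(pos_key)
        og = assignment.get(rec.gene_id)
        if og is None:
            dropped += 1
            continue
        chains.setdefault((rec.genome_id, rec.contig_id), []).append((og, rec))
    genomes = {g for g, _ in chains}
    if len(genomes) < 2:
        raise ValueError(
            f"need at least 2 genomes with assigned genes, got {len(genomes)}"
        )
    gs = GenomeSet(chains)
    gs.report = {
        "n_genomes": len(genomes),
        "n_contigs": len(chains),
        "n_genes": gs.n_genes,
        "n_unassigned_dropped": dropped,
    }
    if dropped:
        log.info("dropped %d genes lacking an orthogroup assignment", dropped)
    return gs


# ---------------------------------------------------------------------------
# tracks and tables
# ---------------------------------------------------------------------------


def write_track(pairs: Iterable[tuple[int, float]], stream: IO[str]) -> None:
    """Write a ``<position>\\t<value>`` track, positions ascending."""
    rows = []
    for pos, value in pairs:
        pos = int(pos)
        if pos < 0:
            raise ValueError(f"negative track position {pos}")
        value = float(value)
        rows.append((pos, value))
    rows.sort(key=lambda r: r[0])
    for pos, value in rows:
        stream.write(f"{pos}\t{value:g}\n")


def read_track(stream: Iterable[str]) -> list[tuple[int, float]]:
    """Read a ``<position>\\t<value>`` track (the custom-track format)."""
    pairs = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"expected '<position>\\t<value>', got {line!r}", lineno)
        try:
            pairs.append((int(fields[0]), float(fields[1])))
        except ValueError as exc:
            raise ParseError(f"non-numeric track entry {line!r}", lineno) from exc
    return pairs


def write_hotspots(regions: Sequence["HotspotRegion"], stream: IO[str]) -> None:
    stream.write("contig\tstart_bp\tend_bp\tn_genes\tmax_complexity\n")
    for region in regions:
        stream.write(
            f"{region.contig_id}\t{region.start_bp}\t{region.end_bp}"
            f"\t{region.n_genes}\t{region.max_complexity:g}\n"
        )


def write_genome_set_tables(
    gs: GenomeSet, gene_table: IO[str], two_column: IO[str]
) -> None:
    """Serialize a genome set as a flat gene table plus a two-column
    gene↔orthogroup file, the formats :func:`parse_gene_annotations` and
    :func:`parse_orthogroup_table` read back."""
    for key in sorted(gs.chains):
        for og, rec in gs.chains[key]:
            gene_table.write(
                f"{rec.gene_id}\t{rec.genome_id}\t{rec.contig_id}\t{rec.start}"
                f"\t{rec.end}\t{rec.strand}\t{rec.product}\n"
            )
            two_column.write(f"{rec.gene_id}\t{og}\n")


# ---------------------------------------------------------------------------
# SQLite persistence (optional)
# ---------------------------------------------------------------------------


def save_sqlite(
    path: str,
    gs: GenomeSet | None = None,
    graph: "GeneGraph | None" = None,
    profile: "ComplexityProfile | None" = None,
) -> None:
    """Persist genes, edges and complexity values in a minimal 3-table schema.

    The text formats remain canonical; this exists for downstream tooling that
    prefers SQL access.
    """
    conn = sqlite3.connect(path)
    try:
        cur = conn.cursor()
        cur.execute(
            "CREATE TABLE IF NOT EXISTS genes ("
            "gene_id TEXT, genome_id TEXT, contig_id TEXT, start INTEGER,"
            " end INTEGER, strand TEXT, product TEXT, orthogroup TEXT)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS edges ("
            "source TEXT, target TEXT, weight INTEGER)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS complexity ("
            "genome_id TEXT, contig_id TEXT, position INTEGER,"
            " node TEXT, value REAL)"
        )
        if gs is not None:
            cur.executemany(
                "INSERT INTO genes VALUES (?,?,?,?,?,?,?,?)",
                [
                    (r.gene_id, r.genome_id, r.contig_id, r.start, r.end,
                     r.strand, r.product, og)
                    for key in sorted(gs.chains)
                    for og, r in gs.chains[key]
                ],
            )
        if graph is not None:
            cur.executemany(
                "INSERT INTO edges VALUES (?,?,?)",
                [(u, v, w) for u, v, w in graph.edges()],
            )
        if profile is not None:
            chain = profile.chain
            cur.executemany(
                "INSERT INTO complexity VALUES (?,?,?,?,?)",
                [
                    (chain.genome_id, chain.contig_id, int(chain.coords[i]),
                     chain.nodes[i], float(profile.values[i]))
                    for i in range(len(chain.nodes))
                ],
            )
        conn.commit()
    finally:
        conn.close()
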