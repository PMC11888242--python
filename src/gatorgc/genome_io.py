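"""GenBank parsing, protein-database construction and annotated window output.

Genomes come in as GenBank flat files with CDS features; they leave as a
structured protein FASTA (one entry per gene, header carrying the genomic
context), per-window annotated GenBank files, and a run summary CSV.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import Contig, GeneRecord, ProteinDbEntry, format_header, make_gene_id

if TYPE_CHECKING:  # pragma: no cover
    from .windows import GatorWindow

logger = logging.getLogger(__name__)

#: NCBI bacterial/plastid translation table used when /translation is absent.
TRANSLATION_TABLE = 11

#: Genes within this many bp of a contig end are flagged as possibly truncated.
DEFAULT_EDGE_BP = 500


def _translate_cds(feature: SeqFeature, record: SeqRecord) -> str | None:
    """Translate a CDS span (exon-joined, strand-aware); None if untranslatable."""
    try:
        nt = feature.location.extract(record.seq)
        aa = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    except Exception as exc:  # malformed location or alphabet
        logger.warning("cannot translate CDS at %s: %s", feature.location, exc)
        return None
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa or not aa:
        return None
    return aa


def parse_genbank(path: str | os.PathLike, genome_id: str | None = None,
                  keep_sequence: bool = True) -> list[Contig]:
    """Parse a (multi-record) GenBank file into Contigs of sorted GeneRecords.

    Every CDS feature becomes a :class:`GeneRecord`. The stored protein is
    the /translation qualifier verbatim when present; otherwise it is
    translated from the nucleotide span with table 11 (one trailing stop
    trimmed). CDS that cannot be translated (internal stop) are skipped
    with a warning. Coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise ValueError(f"cannot read GenBank file {path}: {exc}") from exc
    if not seq_records:
        raise ValueError(f"no GenBank records in {path}")

    contigs: list[Contig] = []
    for record in seq_records:
        try:
            length = len(record.seq)
            sequence = str(record.seq) if keep_sequence else None
        except Exception:  # sequence undefined (CONTIG-only record)
            length = 0
            sequence = None
        genes: list[GeneRecord] = []
        for feature in record.features:
            if feature.type != "CDS":
                continue
            start = int(feature.location.start)
            end = int(feature.location.end)
            strand = 1 if (feature.location.strand or 1) >= 0 else -1
            if len(feature.location.parts) > 1:
                logger.info("multi-exon CDS at %s:%d-%d; using enclosing span",
                            record.id, start, end)
            translation = feature.qualifiers.get("translation", [None])[0]
            if translation is None:
                translation = _translate_cds(feature, record)
                if translation is None:
                    logger.warning("skipping untranslatable CDS %s:%d-%d",
                                   record.id, start, end)
                    continue
            genes.append(GeneRecord(
                gene_id=make_gene_id(genome_id, record.id, start, end, strand),
                contig_id=record.id,
                start=start,
                end=end,
                strand=strand,
                locus_tag=feature.qualifiers.get("locus_tag", [""])[0],
                product=feature.qualifiers.get("product", [""])[0],
                protein_seq=str(translation),
            ))
        if length == 0 and genes:
            length = max(g.end for g in genes)
        contig = Contig(contig_id=record.id, length=length, genome_id=genome_id,
                        genes=genes, sequence=sequence)
        contig.sort_genes()
        contigs.append(contig)
    return contigs


def flag_contig_edges(contigs: Iterable[Contig], edge_bp: int = DEFAULT_EDGE_BP) -> list[Contig]:
    """Set ``contig_edge`` on genes within ``edge_bp`` of either contig end.

    Idempotent; depends only on (start, end, contig length, edge_bp).
    """
    out = list(contigs)
    for contig in out:
        for gene in contig.genes:
            gene.contig_edge = gene.start < edge_bp or (contig.length - gene.end) < edge_bp
    return out


def build_protein_db(contigs: Iterable[Contig],
                     fasta_path: str | os.PathLike | None = None) -> list[ProteinDbEntry]:
    """One FASTA entry per gene, header encoding the genomic context.

    Entries are ordered deterministically by (genome_id, contig_id, start);
    the header round-trips to the source GeneRecord fields (after the
    delimiter sanitization of free text).
    """
    entries: list[ProteinDbEntry] = []
    for contig in sorted(contigs, key=lambda c: (c.genome_id, c.contig_id)):
        for gene in sorted(contig.genes, key=lambda g: g.start):
            entries.append(ProteinDbEntry(header=format_header(contig.genome_id, gene),
                                          sequence=gene.protein_seq))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for entry in entries:
                fh.write(f">{entry.header}\n{entry.sequence}\n")
    return entries


def _safe_filename(window_id: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in window_id)


def write_window_genbank(window: "GatorWindow", out_dir: str | os.PathLike,
                         contig_sequence: str | None = None) -> Path:
    """Write one annotated GenBank file per window under ``out_dir``.

    Each CDS carries /gator_query (required|optional|None), /gator_hit
    (matched query, only when hit), /gator_nrps, /gator_pks and
    /contig_edge qualifiers; coordinates are re-based to the window start.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    span = window.span_end - window.span_start
    if contig_sequence is not None:
        seq = Seq(contig_sequence[window.span_start:window.span_end])
    else:
        seq = Seq("N" * span)
    record = SeqRecord(seq, id=_safe_filename(window.window_id)[:40] or "window",
                       name=_safe_filename(window.window_id)[:16] or "window",
                       description=f"window {window.window_id} "
                                   f"{window.contig_id}:{window.span_start + 1}-{window.span_end}")
    record.annotations["molecule_type"] = "DNA"
    for gene in window.genes:
        start = max(0, gene.start - window.span_start)
        end = min(span, gene.end - window.span_start)
        assignment = window.hit_assignments.get(gene.gene_id)
        category = window.categories.get(gene.gene_id)
        qualifiers = {
            "locus_tag": [gene.locus_tag] if gene.locus_tag else [],
            "product": [gene.product] if gene.product else [],
            "translation": [gene.protein_seq],
            "gator_query": [assignment.role if assignment else "None"],
            "gator_nrps": [str(bool(category and category.is_nrps))],
            "gator_pks": [str(bool(category and category.is_pks))],
            "contig_edge": [str(bool(gene.contig_edge))],
            "gator_window": [window.window_id],
        }
        if assignment:
            qualifiers["gator_hit"] = [assignment.query_id]
        qualifiers = {k: v for k, v in qualifiers.items() if v}
        record.features.append(SeqFeature(
            FeatureLocation(start, end, strand=gene.strand), type="CDS",
            qualifiers=qualifiers))
    out_path = out_dir / f"{_safe_filename(window.window_id)}.gbk"
    SeqIO.write([record], str(out_path), "genbank")
    return out_path


def write_summary_table(windows: Iterable["GatorWindow"],
                        out_path: str | os.PathLike) -> pd.DataFrame:
    """Summary CSV of all query hits, sorted by window id then gene start.

    Coordinates are written 1-based inclusive (GenBank convention).
    """
    rows = []
    for window in sorted(windows, key=lambda w: w.window_id):
        for gene in window.genes:
            assignment = window.hit_assignments.get(gene.gene_id)
            if assignment is None:
                continue
            category = window.categories.get(gene.gene_id)
            rows.append({
                "window_id": window.window_id,
                "query_id": assignment.query_id,
                "gator_query": assignment.role,
                "gator_nrps": bool(category and category.is_nrps),
                "gator_pks": bool(category and category.is_pks),
                "start": gene.start + 1,
                "end": gene.end,
                "strand": "+" if gene.strand >= 0 else "-",
                "locus_tag": gene.locus_tag,
                "contig": gene.contig_id,
                "genome": window.genome_id,
                "contig_edge": gene.contig_edge,
            })
    columns = ["window_id", "query_id", "gator_query", "gator_nrps", "gator_pks",
               "start", "end", "strand", "locus_tag", "contig", "genome", "contig_edge"]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(out_path, index=False)
    return df
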