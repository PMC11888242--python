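"""Core genomic records and the protein-database header codec.

Internal coordinates are 0-based half-open throughout; conversion to the
GenBank 1-based inclusive convention happens only at file boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Reserved delimiter for structured FASTA headers. Free-text fields
#: (locus tags, products) have occurrences replaced by "_".
HEADER_DELIM = "|"


def sanitize_field(text: str) -> str:
    """Replace the reserved header delimiter (and newlines) in free text."""
    return re.sub(r"[|\r\n\t]", "_", text or "")


def make_gene_id(genome_id: str, contig_id: str, start: int, end: int, strand: int) -> str:
    s = "+" if strand >= 0 else "-"
    return f"{genome_id}|{contig_id}|{start}-{end}{s}"


@dataclass
class GeneRecord:
    """One CDS: coordinates, strand, annotation and protein sequence."""

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: int  # +1 / -1
    locus_tag: str = ""
    product: str = ""
    protein_seq: str = ""
    contig_edge: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene span [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def distance_to(self, other: "GeneRecord") -> int:
        """Gap in bp between the two gene spans; overlapping genes -> 0."""
        if self.start < other.start:
            earlier, later = self, other
        else:
            earlier, later = other, self
        return max(0, later.start - earlier.end)


@dataclass
class Contig:
    contig_id: str
    length: int
    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None  # optional nucleotide sequence (for window output)

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))


@dataclass(frozen=True)
class ProteinDbEntry:
    """A protein FASTA entry whose header carries genomic context."""

    header: str
    sequence: str

    @property
    def gene_id(self) -> str:
        f = parse_header(self.header)
        return make_gene_id(f["genome_id"], f["contig_id"], f["start"], f["end"], f["strand"])


def format_header(genome_id: str, gene: GeneRecord) -> str:
    """genome|contig|start|end|strand|locus|product (free text sanitized)."""
    strand = "+" if gene.strand >= 0 else "-"
    parts = [
        sanitize_field(genome_id),
        sanitize_field(gene.contig_id),
        str(gene.start),
        str(gene.end),
        strand,
        sanitize_field(gene.locus_tag),
        sanitize_field(gene.product),
    ]
    return HEADER_DELIM.join(parts)


def parse_header(header: str) -> dict:
    """Invert :func:`format_header`. Raises ValueError on malformed input."""
    parts = header.split(HEADER_DELIM)
    if len(parts) != 7:
        raise ValueError(f"malformed protein header: {header!r}")
    genome_id, contig_id, start, end, strand, locus, product = parts
    return {
        "genome_id": genome_id,
        "contig_id": contig_id,
        "start": int(start),
        "end": int(end),
        "strand": 1 if strand == "+" else -1,
        "locus_tag": locus,
        "product": product,
    }


def gene_from_header(header: str, sequence: str = "") -> GeneRecord:
    f = parse_header(header)
    return GeneRecord(
        gene_id=make_gene_id(f["genome_id"], f["contig_id"], f["start"], f["end"], f["strand"]),
        contig_id=f["contig_id"],
        start=f["start"],
        end=f["end"],
        strand=f["strand"],
        locus_tag=f["locus_tag"],
        product=f["product"],
        protein_seq=sequence,
    )
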