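"""Homology evidence behind one contract.

Hits can come from external aligners (BLAST/DIAMOND 12+-column tabular),
from HMMER-style per-domain tables, or from the built-in deterministic
Smith-Waterman engine (BLOSUM62, affine gaps) that serves desk-scale runs
and acts as the exact oracle in tests. Proteins are classified as
NRPS / PKS / hybrid from their modular domains:

* >=1 adenylation (A) and >=1 condensation (C) domain  -> NRPS
* >=1 acyltransferase (AT) and >=1 ketosynthase (KS)   -> PKS
* both rules satisfied                                  -> HYBRID
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .records import ProteinDbEntry

logger = logging.getLogger(__name__)

DEFAULT_MIN_QCOV = 70.0   # percent of the query covered by the alignment
DEFAULT_MIN_PID = 35.0    # percent identity over the alignment
DEFAULT_MAX_EVALUE = 1e-4  # domain-hit significance cutoff

MODULAR_DOMAINS = ("A", "C", "AT", "KS")

# Gapped BLOSUM62 Karlin-Altschul parameters (gap open 11, extend 1).
_LAMBDA = 0.267
_K = 0.041

#: Default HMM profile-name -> domain mapping for HMMER domain tables.
#: Editable/extensible; antiSMASH profile names shown as examples.
DEFAULT_PROFILE_MAP = {
    "AMP-binding": "A",
    "A-OX": "A",
    "Condensation": "C",
    "PKS_AT": "AT",
    "PKS_KS": "KS",
    "ene_KS": "KS",
    "tra_KS": "KS",
    "A": "A",
    "C": "C",
    "AT": "AT",
    "KS": "KS",
}

#: Literal signature motifs used by :class:`MotifDomainSource` (the
#: deterministic domain caller for synthetic proteins carrying planted tags).
DEFAULT_DOMAIN_MOTIFS = {
    "WCWCWCAD": "A",
    "WCWCWCCD": "C",
    "WCWCWCAT": "AT",
    "WCWCWCKS": "KS",
}


class ModularCategory(Enum):
    NONE = "none"
    NRPS = "nrps"
    PKS = "pks"
    HYBRID = "hybrid"

    @property
    def is_nrps(self) -> bool:
        return self in (ModularCategory.NRPS, ModularCategory.HYBRID)

    @property
    def is_pks(self) -> bool:
        return self in (ModularCategory.PKS, ModularCategory.HYBRID)

    @property
    def is_modular(self) -> bool:
        return self is not ModularCategory.NONE


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    pct_identity: float
    query_cover: float
    evalue: float
    bit_score: float
    q_start: int  # 1-based
    q_end: int
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if not (0.0 <= self.query_cover <= 100.0):
            raise ValueError(f"query_cover out of range: {self.query_cover}")
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain: str  # one of MODULAR_DOMAINS
    evalue: float
    env_start: int  # 1-based
    env_end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.domain not in MODULAR_DOMAINS:
            raise ValueError(f"unknown modular domain {self.domain!r}")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass
class QueryProtein:
    query_id: str
    sequence: str
    role: str  # "required" | "optional"
    category: ModularCategory = ModularCategory.NONE

    def __post_init__(self) -> None:
        if self.role not in ("required", "optional"):
            raise ValueError(f"role must be required/optional, got {self.role!r}")
        if not self.sequence:
            raise ValueError(f"query {self.query_id}: empty sequence")


def read_query_fasta(path: str | os.PathLike, role: str) -> list[QueryProtein]:
    queries = [QueryProtein(rec.id, str(rec.seq).rstrip("*"), role)
               for rec in SeqIO.parse(str(path), "fasta")]
    if not queries:
        raise ValueError(f"no sequences in query FASTA {path}")
    return queries


# ---------------------------------------------------------------------------
# Tabular ingestion
# ---------------------------------------------------------------------------

def load_tabular_hits(path: str | os.PathLike,
                      min_qcov: float = DEFAULT_MIN_QCOV,
                      min_pid: float = DEFAULT_MIN_PID,
                      query_lengths: Mapping[str, int] | None = None) -> list[HomologyHit]:
    """Parse BLAST/DIAMOND outfmt-6 style tabular hits and filter.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore [qcovhsp]. When the 13th query-coverage
    column is absent, coverage is derived as aligned query span / query
    length (requires ``query_lengths``).
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                logger.warning("%s:%d: malformed row (%d cols), skipped",
                               path, lineno, len(cols))
                continue
            try:
                qid, sid = cols[0], cols[1]
                pid = float(cols[2])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue, bits = float(cols[10]), float(cols[11])
                if len(cols) >= 13:
                    qcov = float(cols[12])
                elif query_lengths is not None and qid in query_lengths:
                    qcov = 100.0 * (qend - qstart + 1) / query_lengths[qid]
                else:
                    raise ValueError("no qcovhsp column and no query length")
            except ValueError as exc:
                if "query length" in str(exc):
                    raise ValueError(
                        f"{path}:{lineno}: cannot derive query coverage: {exc}") from exc
                logger.warning("%s:%d: unparsable row, skipped (%s)", path, lineno, exc)
                continue
            if pid < min_pid or qcov < min_qcov:
                continue
            hits.append(HomologyHit(qid, sid, pid, min(qcov, 100.0), evalue, bits,
                                    qstart, qend, sstart, send))
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], path: str | os.PathLike) -> None:
    """Serialize hits in 13-column tabular form (outfmt 6 + qcovhsp)."""
    with open(path, "w") as fh:
        for h in hits:
            # mismatch/gapopen are not tracked; write 0 placeholders.
            aln_len = h.q_end - h.q_start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", aln_len, 0, 0,
                h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.evalue:.3g}", f"{h.bit_score:.1f}", f"{h.query_cover:.2f}",
            ])) + "\n")


def load_domain_hits(path: str | os.PathLike,
                     max_evalue: float = DEFAULT_MAX_EVALUE,
                     profile_map: Mapping[str, str] | None = None) -> list[DomainHit]:
    """Parse a HMMER ``--domtblout``-style per-domain table and filter.

    Whitespace-separated columns; the target (protein) name is column 1,
    the query profile name column 4, the independent e-value column 13,
    the envelope bounds columns 20-21 and the domain score column 14.
    Rows whose profile name is not in ``profile_map`` are ignored.
    """
    profile_map = dict(DEFAULT_PROFILE_MAP if profile_map is None else profile_map)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 21:
                logger.warning("%s:%d: malformed domain row, skipped", path, lineno)
                continue
            profile = cols[3]
            domain = profile_map.get(profile)
            if domain is None:
                logger.info("%s:%d: unknown profile %r ignored", path, lineno, profile)
                continue
            try:
                evalue = float(cols[12])
                score = float(cols[13])
                env_start, env_end = int(cols[19]), int(cols[20])
            except ValueError as exc:
                logger.warning("%s:%d: unparsable domain row (%s)", path, lineno, exc)
                continue
            if evalue > max_evalue:
                continue
            hits.append(DomainHit(cols[0], domain, evalue, env_start, env_end, score))
    return hits


# ---------------------------------------------------------------------------
# Built-in exact search
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_BLOSUM62.alphabet))


def _clean_protein(seq: str) -> str:
    seq = seq.upper().rstrip("*")
    return "".join(c if c in _ALPHABET else "X" for c in seq)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.mode = "local"
    # BLAST affine convention: a gap of length k costs 11 + k.
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def _normalize_proteins(items: Sequence) -> list[tuple[str, str]]:
    out = []
    for item in items:
        if isinstance(item, ProteinDbEntry):
            out.append((item.gene_id, item.sequence))
        elif isinstance(item, QueryProtein):
            out.append((item.query_id, item.sequence))
        elif isinstance(item, tuple) and len(item) == 2:
            out.append((item[0], item[1]))
        else:  # duck-typed record
            out.append((item.gene_id, item.protein_seq))
    return out


def builtin_search(queries: Sequence, db: Sequence,
                   min_qcov: float = DEFAULT_MIN_QCOV,
                   min_pid: float = DEFAULT_MIN_PID) -> list[HomologyHit]:
    """Deterministic all-vs-all local alignment search (desk scale).

    Smith-Waterman with BLOSUM62 and affine gaps; alignments are converted
    to percent identity (identities / alignment columns) and query
    coverage (aligned query span / query length), then filtered with the
    same contract as :func:`load_tabular_hits`. Bit scores and e-values
    use the gapped BLOSUM62 Karlin-Altschul parameters.
    """
    aligner = _make_aligner()
    query_items = _normalize_proteins(queries)
    db_items = _normalize_proteins(db)
    db_residues = max(1, sum(len(s) for _, s in db_items))
    hits: list[HomologyHit] = []
    for qid, qseq_raw in query_items:
        qseq = _clean_protein(qseq_raw)
        if not qseq:
            continue
        for sid, sseq_raw in db_items:
            sseq = _clean_protein(sseq_raw)
            if not sseq:
                continue
            try:
                alignments = aligner.align(qseq, sseq)
            except Exception:  # no positive-scoring alignment
                continue
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            aln = alignments[0]
            counts = aln.counts()
            aln_len = counts.identities + counts.mismatches + counts.gaps
            if aln_len == 0:
                continue
            pid = 100.0 * counts.identities / aln_len
            q_blocks, s_blocks = aln.aligned[0], aln.aligned[1]
            q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
            s_start, s_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
            qcov = 100.0 * (q_end - q_start) / len(qseq)
            if pid < min_pid or qcov < min_qcov:
                continue
            bit = (_LAMBDA * aln.score - math.log(_K)) / math.log(2.0)
            evalue = len(qseq) * db_residues * 2.0 ** (-bit)
            hits.append(HomologyHit(qid, sid, pid, qcov, evalue, bit,
                                    q_start + 1, q_end, s_start + 1, s_end))
    return hits


class BuiltinEngine:
    """Search-engine adapter around :func:`builtin_search`."""

    def __init__(self, min_qcov: float = DEFAULT_MIN_QCOV,
                 min_pid: float = DEFAULT_MIN_PID) -> None:
        self.min_qcov = min_qcov
        self.min_pid = min_pid

    def search(self, queries: Sequence, db: Sequence) -> list[HomologyHit]:
        return builtin_search(queries, db, self.min_qcov, self.min_pid)


class TabularEngine:
    """Engine that serves pre-computed tabular hits (external aligner)."""

    def __init__(self, path: str | os.PathLike,
                 min_qcov: float = DEFAULT_MIN_QCOV,
                 min_pid: float = DEFAULT_MIN_PID) -> None:
        self._path = path
        self.min_qcov = min_qcov
        self.min_pid = min_pid

    def search(self, queries: Sequence, db: Sequence) -> list[HomologyHit]:
        qlens = {qid: len(seq) for qid, seq in _normalize_proteins(queries)}
        ids = set(qlens)
        hits = load_tabular_hits(self._path, self.min_qcov, self.min_pid, qlens)
        return [h for h in hits if h.query_id in ids]


# ---------------------------------------------------------------------------
# Modular-domain classification
# ---------------------------------------------------------------------------

def classify_modularity(domains: Iterable[DomainHit | str]) -> ModularCategory:
    """NRPS/PKS/HYBRID/NONE from a protein's domain complement.

    Counts, not positions, drive the rules; overlapping hits are not merged.
    """
    names = {d.domain if isinstance(d, DomainHit) else d for d in domains}
    nrps = "A" in names and "C" in names
    pks = "AT" in names and "KS" in names
    if nrps and pks:
        return ModularCategory.HYBRID
    if nrps:
        return ModularCategory.NRPS
    if pks:
        return ModularCategory.PKS
    return ModularCategory.NONE


class TableDomainSource:
    """Domain source backed by a pre-loaded list of DomainHits."""

    def __init__(self, hits: Iterable[DomainHit]) -> None:
        self._by_protein: dict[str, list[DomainHit]] = {}
        for hit in hits:
            self._by_protein.setdefault(hit.protein_id, []).append(hit)

    def __call__(self, protein_id: str, sequence: str) -> list[DomainHit]:
        return self._by_protein.get(protein_id, [])


class MotifDomainSource:
    """Literal signature-motif scanner mapping motifs to modular domains.

    A deterministic domain caller for sequences carrying planted signature
    tags (see the synthetic-genome generator); each motif occurrence
    yields one DomainHit with e-value 0.
    """

    def __init__(self, motifs: Mapping[str, str] | None = None) -> None:
        self.motifs = dict(DEFAULT_DOMAIN_MOTIFS if motifs is None else motifs)
        bad = set(self.motifs.values()) - set(MODULAR_DOMAINS)
        if bad:
            raise ValueError(f"motif map targets unknown domains {bad}")

    def __call__(self, protein_id: str, sequence: str) -> list[DomainHit]:
        hits = []
        for motif, domain in sorted(self.motifs.items()):
            pos = sequence.find(motif)
            while pos != -1:
                hits.append(DomainHit(protein_id, domain, 0.0,
                                      pos + 1, pos + len(motif), 100.0))
                pos = sequence.find(motif, pos + 1)
        return hits


DomainSource = Callable[[str, str], list[DomainHit]]


def screen_queries(queries: Sequence[QueryProtein],
                   domain_source: DomainSource) -> tuple[list[QueryProtein], list[QueryProtein]]:
    """Partition queries into (modular, non_modular), storing the category."""
    modular, non_modular = [], []
    for query in queries:
        query.category = classify_modularity(domain_source(query.query_id, query.sequence))
        (modular if query.category.is_modular else non_modular).append(query)
    return modular, non_modular


def categorize_proteins(entries: Sequence, domain_source: DomainSource) -> dict[str, ModularCategory]:
    """ModularCategory per database protein (keyed by gene id)."""
    out = {}
    for pid, seq in _normalize_proteins(entries):
        out[pid] = classify_modularity(domain_source(pid, seq))
    return out


def _category_matches(query_cat: ModularCategory, subject_cat: ModularCategory,
                      strict: bool) -> bool:
    if strict:
        return query_cat is subject_cat
    if query_cat is ModularCategory.HYBRID:
        return subject_cat is ModularCategory.HYBRID
    if query_cat is ModularCategory.NRPS:
        return subject_cat in (ModularCategory.NRPS, ModularCategory.HYBRID)
    if query_cat is ModularCategory.PKS:
        return subject_cat in (ModularCategory.PKS, ModularCategory.HYBRID)
    return False


def build_hit_dictionary(queries: Sequence[QueryProtein],
                         homology_hits: Iterable[HomologyHit],
                         db_categories: Mapping[str, ModularCategory],
                         strict_modular: bool = False) -> dict[str, set[str]]:
    """Map each query id to the set of database gene ids it retrieves.

    Non-modular queries resolve through the (already filtered) similarity
    hits; modular queries resolve through the modular-domains database:
    every DB protein whose category matches the query's (NRPS matches
    NRPS+HYBRID, PKS matches PKS+HYBRID, HYBRID matches HYBRID only;
    ``strict_modular`` switches to exact category equality).
    """
    by_query: dict[str, set[str]] = {q.query_id: set() for q in queries}
    hit_lookup: dict[str, set[str]] = {}
    for hit in homology_hits:
        hit_lookup.setdefault(hit.query_id, set()).add(hit.subject_id)
    for query in queries:
        if query.category.is_modular:
            by_query[query.query_id] = {
                gid for gid, cat in db_categories.items()
                if _category_matches(query.category, cat, strict_modular)}
        else:
            by_query[query.query_id] = set(hit_lookup.get(query.query_id, set()))
    return by_query
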