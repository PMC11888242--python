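"""End-to-end orchestration behind the two-command workflow.

``pre``  : parse genomes, build the context-header protein database and
           the modular-domain category table.
``mine`` : screen queries, search, call and annotate windows, deduplicate,
           compute presence-absence / focal scores / diversity, and write
           the full output tree (CSV tables, annotated GenBank files,
           SVG figures) plus a resolved-config echo.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diversity as div
from . import genome_io, homology, scoring, visualization, windows as win

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_paths: list[str] = field(default_factory=list)
    required_fasta: str = ""
    optional_fasta: str | None = None
    out_dir: str = "gator_out"
    query_cover: float = homology.DEFAULT_MIN_QCOV
    identity: float = homology.DEFAULT_MIN_PID
    e_value: float = homology.DEFAULT_MAX_EVALUE
    required_distance: int = win.DEFAULT_REQUIRED_DISTANCE
    window_extension: int = win.DEFAULT_WINDOW_EXTENSION
    edge_distance: int = win.DEFAULT_EDGE_BP
    sigma: float | None = None          # None -> max(1, n_genes/6) per window
    dedup_mutual: bool = False
    merge_overlapping: bool = True
    linkage: str = "single"
    strict_modular: bool = False
    conservation_on_all: bool = False   # default: deduplicated set
    taxonomy_tsv: str | None = None
    taxonomy_level: str = "genus"
    domain_table: str | None = None     # HMMER domtblout-style table
    domain_motifs: str | None = None    # TSV motif -> domain
    hits_table: str | None = None       # external query-vs-db tabular hits
    window_hits_table: str | None = None  # external window-vs-window hits
    figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.query_cover <= 100 and 0 <= self.identity <= 100):
            raise ValueError("thresholds must be percentages in [0, 100]")
        if min(self.required_distance, self.window_extension, self.edge_distance) < 0:
            raise ValueError("distances must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _domain_source(config: RunConfig) -> homology.DomainSource:
    if config.domain_table:
        hits = homology.load_domain_hits(config.domain_table, config.e_value)
        return homology.TableDomainSource(hits)
    if config.domain_motifs:
        motifs = {}
        with open(config.domain_motifs) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                motif, domain = line.split("\t")[:2]
                motifs[motif] = domain
        return homology.MotifDomainSource(motifs)
    return homology.MotifDomainSource()  # default signature motifs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def pre(genome_paths: list[str | Path], out_dir: str | Path,
        domain_source: homology.DomainSource | None = None,
        edge_bp: int = win.DEFAULT_EDGE_BP) -> dict:
    """Build the protein database and the modular-category table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = []
    for path in sorted(str(p) for p in genome_paths):
        contigs.extend(genome_io.parse_genbank(path))
    if not any(c.genes for c in contigs):
        raise ValueError("no CDS features found in the input genomes")
    genome_io.flag_contig_edges(contigs, edge_bp)
    fasta = out_dir / "proteins.faa"
    entries = genome_io.build_protein_db(contigs, fasta)
    source = domain_source or homology.MotifDomainSource()
    categories = homology.categorize_proteins(entries, source)
    cat_path = out_dir / "modular_categories.tsv"
    with open(cat_path, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gid in sorted(categories):
            fh.write(f"{gid}\t{categories[gid].value}\n")
    manifest = {
        "n_genomes": len({c.genome_id for c in contigs}),
        "n_contigs": len(contigs),
        "n_proteins": len(entries),
        "files": {p.name: _sha256(p) for p in (fasta, cat_path)},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclass
class MineResult:
    windows: list[win.GatorWindow]
    unique: list[win.GatorWindow]
    dedup: scoring.DeduplicationMap
    gfs_matrix: scoring.GfsMatrix | None
    presence: dict[str, scoring.PresenceAbsence]
    summary: pd.DataFrame
    out_dir: Path


def mine(config: RunConfig) -> MineResult:
    """Run the full mining workflow and write the output tree."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(config.to_json())

    contigs = []
    for path in sorted(str(p) for p in config.genome_paths):
        contigs.extend(genome_io.parse_genbank(path))
    genome_io.flag_contig_edges(contigs, config.edge_distance)
    entries = genome_io.build_protein_db(contigs)
    contig_seq = {(c.genome_id, c.contig_id): c.sequence for c in contigs}

    queries = homology.read_query_fasta(config.required_fasta, "required")
    if config.optional_fasta:
        queries += homology.read_query_fasta(config.optional_fasta, "optional")
    seen = set()
    for q in queries:
        if q.query_id in seen:
            raise ValueError(f"duplicate query id {q.query_id}")
        seen.add(q.query_id)
    required_ids = [q.query_id for q in queries if q.role == "required"]
    optional_ids = [q.query_id for q in queries if q.role == "optional"]

    source = _domain_source(config)
    modular, non_modular = homology.screen_queries(queries, source)
    categories = homology.categorize_proteins(entries, source)

    if config.hits_table:
        engine = homology.TabularEngine(config.hits_table,
                                        config.query_cover, config.identity)
    else:
        engine = homology.BuiltinEngine(config.query_cover, config.identity)
    query_hits = engine.search(non_modular, entries) if non_modular else []
    hit_dict = homology.build_hit_dictionary(queries, query_hits, categories,
                                             config.strict_modular)

    params = win.WindowParams(config.required_distance, config.window_extension,
                              config.edge_distance)
    called = win.call_windows(contigs, hit_dict, required_ids, optional_ids,
                              params, linkage=config.linkage,
                              merge_overlapping=config.merge_overlapping,
                              categories=categories,
                              scores=win.hit_scores(query_hits))

    gbk_dir = out_dir / "windows_genbanks"
    gbk_dir.mkdir(exist_ok=True)
    for window in called:
        genome_io.write_window_genbank(
            window, gbk_dir,
            contig_sequence=contig_seq.get((window.genome_id, window.contig_id)))
    summary = genome_io.write_summary_table(called, out_dir / "gator_summary.csv")

    if not called:
        logger.warning("no windows identified; nothing to score")
        (out_dir / "no_windows.txt").write_text(
            "No window satisfied all required queries under the given "
            "distance cutoff.\n")
        return MineResult([], [], scoring.DeduplicationMap(), None, {},
                          summary, out_dir)

    if config.window_hits_table:
        window_engine = homology.TabularEngine(config.window_hits_table,
                                               config.query_cover, config.identity)
    else:
        window_engine = homology.BuiltinEngine(config.query_cover, config.identity)
    matrix, tables = scoring.all_vs_all(called, window_engine, sigma=config.sigma)
    unique, dedup = scoring.deduplicate(called, window_engine,
                                        mutual=config.dedup_mutual,
                                        sigma=config.sigma, precomputed=tables)
    scoring.export_scores(matrix, tables, dedup, out_dir)

    basis = called if config.conservation_on_all else unique
    basis_ids = [w.window_id for w in basis]
    profiles = {}
    for window in basis:
        sub = scoring.PresenceAbsence(
            window.window_id, tables[window.window_id].matrix.loc[basis_ids])
        profiles[window.window_id] = visualization.conservation_profile(window, sub)

    if config.taxonomy_tsv:
        taxonomy = div.load_taxonomy(config.taxonomy_tsv)
        rows = []
        for level in taxonomy.columns:
            counts = div.family_counts([w.genome_id for w in called], taxonomy,
                                       level, family_id="all_windows")
            rows.append({"level": level, "n_taxa": counts.n_taxa,
                         "H_bits": div.shannon_entropy(counts)})
        pd.DataFrame(rows).to_csv(out_dir / "diversity.csv", index=False)

    if config.figures:
        window_proteins = [p for w in called for p in w.proteins()]
        window_hits = window_engine.search(window_proteins, window_proteins)
        for window in basis:
            visualization.draw_conservation(
                window, profiles[window.window_id],
                out_dir / "gator_conservation_plots" /
                f"{scoring._safe(window.window_id)}.svg")
            visualization.draw_neighborhood(
                window, basis, matrix.values[window.window_id].to_dict(),
                window_hits,
                out_dir / "gator_neighborhood_plots" /
                f"{scoring._safe(window.window_id)}.svg")
        if len(basis_ids) >= 1:
            sub_matrix = scoring.GfsMatrix(matrix.values.loc[basis_ids, basis_ids])
            order = div.cluster_gfs(sub_matrix.values)
            visualization.draw_heatmap(sub_matrix, order,
                                       out_dir / "concatenated_scores" /
                                       "gfs_heatmap.svg")

    return MineResult(called, unique, dedup, matrix, tables, summary, out_dir)
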