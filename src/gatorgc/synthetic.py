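"""Deterministic synthetic genomes with planted gene clusters.

The generator emulates the inputs the mining pipeline consumes:
multi-contig GenBank genomes carrying a shared cluster template (required
/ optional / filler genes with controlled spacing), exact duplicate
copies, gene-dropout variants, point-mutated variants of known identity,
decoy clusters missing a required gene, and contig-edge truncations.
Ground truth (expected windows, duplicate groups, per-gene conservation)
is emitted alongside, so every pipeline stage can be checked against
construction. Under a fixed seed the output is byte-identical.

It does not model codon usage, GC content, real intergenic grammar or
sequencing artifacts; filler proteins are uniform-random over the 20
amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One fixed codon per amino acid (translation table 11 compatible).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

_MODULAR_TAGS = {
    "nrps": ("WCWCWCAD", "WCWCWCCD"),
    "pks": ("WCWCWCAT", "WCWCWCKS"),
    "hybrid": ("WCWCWCAD", "WCWCWCCD", "WCWCWCAT", "WCWCWCKS"),
}

_GENERA = ["Streptomyces", "Pseudomonas", "Bacillus", "Klebsiella",
           "Mycobacterium", "Burkholderia", "Escherichia", "Nocardia"]


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Substitution-mutated variant at a controlled global identity.

    ``round(L * (1 - target/100))`` positions are substituted with a
    different residue, so the achieved identity (matching positions / L)
    is within rounding of the target; it is verified to be within +/- 2
    percentage points, else a ValueError is raised (very short sequences
    cannot reach arbitrary targets).
    """
    if not (0 < target_identity <= 100):
        raise ValueError("target_identity must be in (0, 100]")
    n = len(seq)
    n_mut = round(n * (1.0 - target_identity / 100.0))
    if n_mut == 0:
        return seq
    if n_mut > n:
        raise ValueError("unreachable identity target")
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    variant = "".join(out)
    achieved = 100.0 * sum(a == b for a, b in zip(seq, variant)) / n
    if abs(achieved - target_identity) > 2.0:
        raise ValueError(
            f"achieved identity {achieved:.1f}% misses target {target_identity}%")
    return variant


@dataclass
class TemplateGene:
    name: str
    role: str  # required | optional | filler
    protein: str
    modular: str | None = None  # nrps | pks | hybrid


@dataclass
class PlantSpec:
    """Study conditions for one synthetic dataset (all values in the units
    a desk-scale run of the pipeline expects: bp for distances, aa for
    protein lengths)."""

    seed: int = 0
    n_genomes: int = 5
    #: extra contigs (beyond the cluster-bearing one) carry background genes only
    contigs_per_genome: int = 1
    n_required: int = 3
    n_optional: int = 2
    n_filler: int = 3
    protein_length: int = 80
    gap_range: tuple[int, int] = (200, 2000)
    background_genes: int = 6
    #: clear DNA left between the cluster and any background gene; must
    #: exceed the window extension so duplicates stay exact.
    clear_margin: int = 12_000
    dropouts: dict[int, list[str]] = field(default_factory=dict)
    mutations: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    #: genomes that carry only a decoy cluster (first required gene missing)
    decoy_genomes: list[int] = field(default_factory=list)
    #: genomes whose cluster is truncated at the contig start (< 500 bp)
    edge_truncate: list[int] = field(default_factory=list)
    modular_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_required < 1:
            raise ValueError("need at least one required gene")
        if self.gap_range[0] > self.gap_range[1] or self.gap_range[0] < 0:
            raise ValueError("bad gap_range")
        for g in list(self.dropouts) + list(self.mutations) + \
                self.decoy_genomes + self.edge_truncate:
            if not (0 <= g < self.n_genomes):
                raise ValueError(f"genome index {g} out of range")
        known = {f"R{i + 1}" for i in range(self.n_required)} | \
                {f"O{i + 1}" for i in range(self.n_optional)} | \
                {f"F{i + 1}" for i in range(self.n_filler)}
        for names in self.dropouts.values():
            bad = set(names) - known
            if bad:
                raise ValueError(f"dropout of unknown template genes {bad}")
        for pairs in self.mutations.values():
            bad = {n for n, _ in pairs} - known
            if bad:
                raise ValueError(f"mutation of unknown template genes {bad}")


@dataclass
class SyntheticDataset:
    out_dir: Path
    genome_paths: list[Path]
    required_fasta: Path
    optional_fasta: Path
    taxonomy_path: Path
    template: list[TemplateGene]
    truth_windows: pd.DataFrame
    truth_conservation: pd.DataFrame
    cluster_gaps: list[int]

    @property
    def required_ids(self) -> list[str]:
        return [g.name for g in self.template if g.role == "required"]

    @property
    def optional_ids(self) -> list[str]:
        return [g.name for g in self.template if g.role == "optional"]


def _build_template(spec: PlantSpec, rng: np.random.Generator) -> list[TemplateGene]:
    genes: list[TemplateGene] = []
    for i in range(spec.n_required):
        genes.append(TemplateGene(f"R{i + 1}", "required",
                                  random_protein(rng, spec.protein_length)))
    for i in range(spec.n_optional):
        genes.append(TemplateGene(f"O{i + 1}", "optional",
                                  random_protein(rng, spec.protein_length)))
    for i in range(spec.n_filler):
        genes.append(TemplateGene(f"F{i + 1}", "filler",
                                  random_protein(rng, spec.protein_length)))
    for gene in genes:
        tag = spec.modular_genes.get(gene.name)
        if tag is not None:
            if tag not in _MODULAR_TAGS:
                raise ValueError(f"unknown modular tag {tag!r} for {gene.name}")
            gene.modular = tag
            tags = "".join(_MODULAR_TAGS[tag])
            gene.protein = tags + gene.protein[len(tags):]
    # deterministic interleaving: required genes spread across the cluster
    order = sorted(genes, key=lambda g: (hash_name(g.name), g.name))
    return order


def hash_name(name: str) -> int:
    """Stable small hash used only to interleave template gene order."""
    return sum(ord(c) * (i + 3) for i, c in enumerate(name)) % 7


def _gene_dna(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + _STOP


def _layout_genes(genes: list[tuple[str, str, int]], gaps: list[int],
                  start: int) -> list[tuple[str, str, int, int, int]]:
    """(name, protein, strand) + inter-gene gaps -> placed spans."""
    placed = []
    pos = start
    for k, (name, protein, strand) in enumerate(genes):
        if k > 0:
            pos += gaps[k - 1]
        length = 3 * (len(protein) + 1)
        placed.append((name, protein, strand, pos, pos + length))
        pos += length
    return placed


def generate(spec: PlantSpec, out_dir: str | Path) -> SyntheticDataset:
    """Write genomes, query FASTAs, taxonomy and ground-truth tables."""
    out_dir = Path(out_dir)
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    template = _build_template(spec, rng)

    # Cluster geometry is drawn once so exact copies share their layout.
    cluster_gaps = [int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
                    for _ in range(len(template) - 1)]
    strands = [1 if rng.random() < 0.7 else -1 for _ in template]

    genome_paths: list[Path] = []
    truth_rows = []
    window_contents: list[list[str]] = []  # per expected window: member gene names
    for g in range(spec.n_genomes):
        genome_id = f"g{g + 1:03d}"
        grng = np.random.default_rng(spec.seed + 100_000 + g)
        is_decoy = g in spec.decoy_genomes
        dropped = set(spec.dropouts.get(g, []))
        if is_decoy:
            dropped = dropped | {template[0].name if template[0].role == "required"
                                 else next(t.name for t in template
                                           if t.role == "required")}
        mutated = dict(spec.mutations.get(g, []))

        members: list[tuple[str, str, int]] = []
        member_names: list[str] = []
        gaps: list[int] = []
        for idx, tgene in enumerate(template):
            if tgene.name in dropped:
                continue
            protein = tgene.protein
            if tgene.name in mutated:
                protein = mutate_protein(protein, mutated[tgene.name],
                                         seed=spec.seed + 7_000 + g)
            if members:
                # accumulate gaps over skipped genes to keep spacing stable
                gaps.append(sum(cluster_gaps[j] for j in range(last_idx, idx)))
            members.append((tgene.name, protein, strands[idx]))
            member_names.append(tgene.name)
            last_idx = idx

        lead_bg = spec.background_genes // 2
        trail_bg = spec.background_genes - lead_bg
        pos = 0
        placed: list[tuple[str, str, int, int, int]] = []
        if g in spec.edge_truncate:
            cluster_start = 100
        else:
            bg_genes = [(f"{genome_id}_bgA{i + 1}",
                         random_protein(grng, spec.protein_length), 1)
                        for i in range(lead_bg)]
            bg_gaps = [int(grng.integers(*spec.gap_range)) for _ in range(max(0, lead_bg - 1))]
            placed += _layout_genes(bg_genes, bg_gaps, start=500)
            pos = placed[-1][4] if placed else 500
            cluster_start = pos + spec.clear_margin
        cluster_placed = _layout_genes(members, gaps, start=cluster_start)
        placed += cluster_placed
        pos = cluster_placed[-1][4] if cluster_placed else cluster_start
        bg_genes = [(f"{genome_id}_bgB{i + 1}",
                     random_protein(grng, spec.protein_length), 1)
                    for i in range(trail_bg)]
        bg_gaps = [int(grng.integers(*spec.gap_range)) for _ in range(max(0, trail_bg - 1))]
        placed += _layout_genes(bg_genes, bg_gaps, start=pos + spec.clear_margin)
        contig_len = placed[-1][4] + 2_000

        seq = list("".join(grng.choice(list("ACGT"), size=contig_len)))
        record = SeqRecord(Seq(""), id=f"{genome_id}_c1", name=f"{genome_id}_c1",
                           description=f"synthetic contig of {genome_id}")
        record.annotations["molecule_type"] = "DNA"
        for name, protein, strand, start, end in placed:
            dna = _gene_dna(protein)
            if strand == -1:
                dna = str(Seq(dna).reverse_complement())
            seq[start:end] = list(dna)
            record.features.append(SeqFeature(
                FeatureLocation(start, end, strand=strand), type="CDS",
                qualifiers={"locus_tag": [f"{genome_id}_{name}"],
                            "product": [f"synthetic {name}"],
                            "translation": [protein]}))
        record.seq = Seq("".join(seq))
        records = [record]
        for extra in range(2, spec.contigs_per_genome + 1):
            bg = [(f"{genome_id}_c{extra}_bg{i + 1}",
                   random_protein(grng, spec.protein_length), 1)
                  for i in range(3)]
            bg_gaps = [int(grng.integers(*spec.gap_range)) for _ in range(2)]
            extra_placed = _layout_genes(bg, bg_gaps, start=600)
            extra_len = extra_placed[-1][4] + 1_000
            eseq = list("".join(grng.choice(list("ACGT"), size=extra_len)))
            erec = SeqRecord(Seq(""), id=f"{genome_id}_c{extra}",
                             name=f"{genome_id}_c{extra}",
                             description=f"synthetic contig of {genome_id}")
            erec.annotations["molecule_type"] = "DNA"
            for name, protein, strand, start, end in extra_placed:
                dna = _gene_dna(protein)
                eseq[start:end] = list(dna)
                erec.features.append(SeqFeature(
                    FeatureLocation(start, end, strand=strand), type="CDS",
                    qualifiers={"locus_tag": [f"{genome_id}_{name}"],
                                "product": [f"synthetic {name}"],
                                "translation": [protein]}))
            erec.seq = Seq("".join(eseq))
            records.append(erec)
        path = out_dir / "genomes" / f"{genome_id}.gbk"
        SeqIO.write(records, str(path), "genbank")
        genome_paths.append(path)

        required_present = {m[0] for m in members} & {
            t.name for t in template if t.role == "required"}
        n_required = sum(1 for t in template if t.role == "required")
        if len(required_present) == n_required:
            req_spans = [(s, e) for name, _, _, s, e in cluster_placed
                         if name.startswith("R")]
            truth_rows.append({
                "genome_id": genome_id,
                "contig_id": f"{genome_id}_c1",
                "core_start": min(s for s, _ in req_spans),
                "core_end": max(e for _, e in req_spans),
                "genes": ";".join(member_names),
                "dup_key": "|".join(f"{n}:{p}" for n, p, _ in members),
            })
            window_contents.append(member_names)

    truth_windows = pd.DataFrame(truth_rows)
    if not truth_windows.empty:
        keys = {k: f"dup{i + 1}" for i, k in
                enumerate(dict.fromkeys(truth_windows["dup_key"]))}
        truth_windows["dup_group"] = truth_windows["dup_key"].map(keys)
        truth_windows = truth_windows.drop(columns=["dup_key"])

    cons_rows = []
    n_windows = len(window_contents)
    for tgene in template:
        present = sum(1 for names in window_contents if tgene.name in names)
        cons_rows.append({"gene": tgene.name, "role": tgene.role,
                          "expected_conservation":
                              present / n_windows if n_windows else float("nan")})
    truth_conservation = pd.DataFrame(cons_rows)

    req_path = out_dir / "required.faa"
    opt_path = out_dir / "optional.faa"
    with open(req_path, "w") as fh:
        for t in template:
            if t.role == "required":
                fh.write(f">{t.name}\n{t.protein}\n")
    with open(opt_path, "w") as fh:
        for t in template:
            if t.role == "optional":
                fh.write(f">{t.name}\n{t.protein}\n")

    tax_path = out_dir / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        fh.write("genome_id\tphylum\tgenus\n")
        for g in range(spec.n_genomes):
            genus = _GENERA[g % len(_GENERA)]
            phylum = "Actinomycetota" if g % 2 == 0 else "Pseudomonadota"
            fh.write(f"g{g + 1:03d}\t{phylum}\t{genus}\n")

    truth_windows.to_csv(out_dir / "truth_windows.tsv", sep="\t", index=False)
    truth_conservation.to_csv(out_dir / "truth_conservation.tsv", sep="\t", index=False)

    return SyntheticDataset(
        out_dir=out_dir, genome_paths=genome_paths,
        required_fasta=req_path, optional_fasta=opt_path,
        taxonomy_path=tax_path, template=template,
        truth_windows=truth_windows, truth_conservation=truth_conservation,
        cluster_gaps=cluster_gaps)
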