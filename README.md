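# gatorgc

Targeted genome mining for gene clusters — groups of physically adjacent
genes that work together, such as biosynthetic gene clusters (BGCs) — across
many bacterial genomes at once. Instead of pre-defined detection rules, the
user supplies the proteins that define the cluster of interest: **required**
queries (core enzymes that must all be present) and **optional** queries
(tailoring enzymes, transporters — informative but not definitive). The tool
finds every genomic window satisfying the required set, compares all windows
to each other with a proximity-weighted similarity score, removes identical
windows, quantifies gene-level conservation and taxonomic diversity, and
draws publication-ready vector figures.

It is aimed at natural-product and mobile-element researchers who want to
map the diversity of a known or hypothesized cluster family across genome
collections, including non-canonical clusters that rule-based miners miss.

## Method

**Window calling.** Genomes (GenBank flat files) are parsed into a protein
database whose FASTA headers carry the genomic context
(`genome|contig|start|end|strand|locus|product`). Query proteins are screened
for modular biosynthetic domains — NRPS adenylation (A) and condensation (C),
PKS acyltransferase (AT) and ketosynthase (KS) — and classified: ≥1 A and
≥1 C ⇒ NRPS; ≥1 AT and ≥1 KS ⇒ PKS; both ⇒ hybrid. Non-modular queries are
matched to database proteins by local alignment filtered at 70 % query
coverage and 35 % identity (defaults, adjustable); modular queries match all
database proteins of compatible modular category. A window is called on a
contig when the genes hit by required queries, chained with an inter-gene gap
cutoff (default 85.9 kb, the 95th percentile of intra-cluster gene distances
in experimentally validated BGCs), jointly cover **every** required query.
The core span is extended by 10 kb on each side (clamped to the contig), and
genes within 500 bp of a contig end are flagged as possibly truncated.

**GATOR focal score (GFS).** For a focal window with genes indexed
`i = 0..n−1` and query-anchored genes `q`, each gene gets weight

    w_i = max_q exp( −(i − q)² / (2σ²) ),   σ = max(1, n/6)

so anchors weigh exactly 1 and weights decay with distance from the nearest
anchor. The score of any other window `t` is

    GFS(focal → t) = Σ_i w_i · present_i(t) / Σ_i w_i ∈ [0, 1]

where `present_i(t)` is gene-level presence (≥1 passing homology hit of
focal gene `i` to any protein of `t`). Windows scoring exactly 1.0 against a
longer focal window are deduplicated (processed in descending genomic
length). Conservation of each focal gene is its presence fraction across the
(deduplicated) window set, rendered as fill opacity in the conservation
diagrams. Window-family diversity across taxa is Shannon entropy
`H = −Σ p_i log₂ p_i`, categorized low/medium/high against the
interquartile range of the H distribution. The all-vs-all GFS matrix is
hierarchically clustered (Euclidean distance, complete linkage) for the
heatmap.

## Worked example

Generate a small synthetic dataset with a planted cluster (five exact
copies, one variant missing optional gene `O2`, one decoy genome missing a
required gene) and mine it:

```python
from gatorgc import synthetic, pipeline

spec = synthetic.PlantSpec(seed=1, n_genomes=7,
                           dropouts={5: ["O2"]}, decoy_genomes=[6])
ds = synthetic.generate(spec, "demo_fixture")
result = pipeline.mine(pipeline.RunConfig(
    genome_paths=[str(p) for p in ds.genome_paths],
    required_fasta=str(ds.required_fasta),
    optional_fasta=str(ds.optional_fasta),
    taxonomy_tsv=str(ds.taxonomy_path),
    out_dir="demo_out"))
print(len(result.windows), len(result.unique))
```

prints `6 2`: six windows (the decoy is correctly rejected because one
required query is missing), collapsing to two representatives — the five
identical copies deduplicate to one (all pairwise GFS = 1.0), while the
dropout variant scores 0.854 against them and stays. The same run from the
shell:

```bash
gator mine -g demo_fixture/genomes/*.gbk \
           -r demo_fixture/required.faa -p demo_fixture/optional.faa \
           --taxonomy demo_fixture/taxonomy.tsv -o demo_out
# 6 window(s), 2 unique after deduplication -> demo_out
```

`demo_out/` then contains annotated per-window GenBank files
(`windows_genbanks/`, with `/gator_query`, `/gator_hit`, `/gator_nrps`,
`/gator_pks`, `/contig_edge` qualifiers), per-focal presence–absence tables
(`presence_absence/`), GFS tables (`gator_scores/`), the concatenated score
matrix and clustered heatmap (`concatenated_scores/`), the deduplication log
(`deduplication_process/`), conservation and neighborhood SVGs
(`gator_conservation_plots/`, `gator_neighborhood_plots/`), a summary CSV
and the resolved run configuration (`run_config.json`, re-runnable via
`gator mine --config`).

A two-stage workflow is also available: `gator pre -g genome.gbk -o db`
builds the context-header protein FASTA and the modular-category table with
a checksummed manifest.

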