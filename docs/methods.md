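# Methods

## Data model and coordinates

All internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted at file boundaries only, which keeps every distance
computation (gaps, spans, flank extensions) free of off-by-one ambiguity.
Each CDS becomes a `GeneRecord` (contig, span, strand, locus tag, product,
protein). When a CDS lacks a `/translation` qualifier the protein is
translated from the (exon-joined, strand-aware) nucleotide span with
translation table 11; one trailing stop is trimmed and sequences with
internal stops are skipped with a warning. When `/translation` is present it
is stored verbatim — no re-translation. Compound (join) locations use the
minimal enclosing span for coordinates but the exon-joined sequence for
translation. Non-CDS features and pseudogenes without a usable protein are
ignored. Protein-database headers are pipe-delimited
(`genome|contig|start|end|strand|locus|product`); pipes inside free-text
fields are replaced with `_` so headers always round-trip.

## Homology evidence

Three interchangeable sources sit behind one hit contract
(query id, subject id, % identity, % query coverage, e-value, bit score,
alignment coordinates):

* **Tabular ingestion** of BLAST/DIAMOND outfmt-6 files (12 columns, with
  an optional 13th query-coverage column; coverage is otherwise derived as
  aligned query span / query length, which matches DIAMOND's
  `--query-cover` semantics).
* **HMMER-style per-domain tables** for modular-domain evidence, filtered
  at e-value ≤ 1e-4 by default. The profile-name → domain map is an
  editable table (the shipped defaults name common A/C/AT/KS profiles);
  unknown profiles are ignored with a log line.
* **A built-in Smith–Waterman engine** (Bio.Align.PairwiseAligner, BLOSUM62,
  local mode). Gap costs follow the common affine convention in which a gap
  of length k costs 11 + k. Percent identity is identities over alignment
  columns (gaps included), coverage is the aligned query span over the
  query length. Bit scores and e-values use the gapped BLOSUM62
  Karlin–Altschul parameters (λ = 0.267, K = 0.041). The engine is exact and
  deterministic; it is the default for desk-scale runs and the oracle the
  tests align everything else against. It is quadratic in the number of
  proteins and not intended for large databases — that is what external
  aligners are for.

Default similarity thresholds are 70 % query coverage and 35 % identity,
both exposed on the CLI. Filtering is monotone by construction: raising
either threshold can only remove hits.

Modular classification is rule-based on the domain complement of a protein:
≥1 A and ≥1 C ⇒ NRPS, ≥1 AT and ≥1 KS ⇒ PKS, both ⇒ hybrid, else none.
Counts, not positions, drive the rules; overlapping domain hits are not
merged. Modular queries retrieve database proteins by category rather than
by alignment, because modular megasynthases cross-match promiscuously at
the sequence level. Category matching is permissive by default (an NRPS
query matches NRPS and hybrid subjects, a hybrid query matches hybrids
only); `strict_modular` switches to exact equality.

Because HMM profile databases cannot be redistributed here, a deterministic
signature-motif domain caller (`MotifDomainSource`) ships for synthetic
data: literal 8-mer tags (e.g. `WCWCWCAD` for A) planted into generated
proteins. The chance of such a tag arising in a random background protein
is ~20⁻⁸ per position, so synthetic domain truth is unambiguous. Real
datasets should use HMMER domain tables instead.

## Window calling

Per contig, the genes hit by required queries are chained so that
consecutive genes are within the distance cutoff (gap = `max(0,
later.start − earlier.end)`; overlapping genes have gap 0). Single-linkage
chaining (gap to the nearest chain member) is the default and is provably
equivalent to connected components of the pairwise gap graph — the test
suite checks this equivalence against an independent graph implementation
on random genomes. A stricter complete-linkage mode (gap to the farthest
member) is available as a flag. A chain yields a window iff the union of
its genes' hits covers every required query. The core span over the chain
is extended by the window extension (default 10 kb) on both sides, clamped
to the contig; every gene overlapping the extended span joins the window
(partial overlap suffices, so a boundary gene may protrude past the span).
Windows whose extended spans overlap on one contig are merged by default
(toggleable) to avoid double-counting in the all-vs-all comparison.

The default distance cutoff of 85,900 bp is the 95th percentile (linear
interpolation) of pooled pairwise intra-cluster gene distances over a
curated set of experimentally validated BGCs; `estimate_default_distance`
implements the estimator so it can be recomputed on any reference cluster
set. Window ids are `<genome>|<contig>|w<k>` with k by ascending span
start (zero-padded for lexicographic sortability).

A gene claimed by several queries is assigned by precedence required >
optional, ties broken by the higher bit score when scores are available,
then lexicographic query id.

## Focal scoring, deduplication, conservation

Weights live in gene-ordinal space by default: `w_i = max_q
exp(−(i−q)²/(2σ²))` over anchor ordinals q, with σ = max(1, n/6). Ordinal
space makes the score invariant to intergenic-length noise; with σ = n/6 an
anchor at one window edge decays to ≈e⁻¹⁸ at the far edge. A bp-based mode
(σ in bp, distances between gene midpoints) is available for users who want
physical-distance weighting. Anchor weights are set to exactly 1.0 (not
merely within float error) because the self-score identity `GFS(w, w) = 1`
is load-bearing for deduplication.

Presence is boolean per focal gene — one passing hit to any protein of the
target window suffices, and multiplicity does not inflate the score. The
score of a target is the weighted presence ratio, so it is bounded in
[0, 1], equals 1 on the window itself, and is monotone under presence-bit
flips (all three are property-tested).

Deduplication processes focal windows by genomic length descending (ties:
lexicographic id). Any not-yet-processed window scoring ≥ 1 − 1e-9 against
the current focal is removed and mapped to it. Windows that already served
as focal are final representatives and cannot be removed later: under
one-directional scoring a shorter window whose gene content is a strict
subset of a longer one scores 1.0 against it, and without this rule it
would evict the longer representative when its own turn came. A `mutual`
mode additionally requires the reverse score to be 1.0 before removal.
Because the presence of a focal gene in a target depends only on that pair,
presence tables computed once stay exact as windows leave the pool.

Per-gene conservation is the column mean of the focal window's
presence-absence table; by default the table is restricted to the
deduplicated window set (a flag switches to all windows, which biases
conservation toward heavily duplicated clones).

## Diversity and clustering

Shannon entropy is computed in bits over taxon counts at a user-chosen rank
(relative abundances of the family's windows per taxon; zero-count taxa
contribute nothing). Entropy values across families are categorized against
their own distribution: Q1/Q3 by linear interpolation, low for H ≤ Q3
(values below Q1 are low-diversity by construction), medium up to the right
whisker Q3 + 1.5·IQR, high beyond it. With fewer than four families the
quartiles are meaningless and everything is labeled low with a warning.
Taxonomy is supplied as a TSV (id → one column per rank); no taxonomic
inference is performed.

The score matrix is clustered on row vectors with Euclidean distances and
complete linkage (scipy); the dendrogram leaf order drives the heatmap
permutation.

## Figures

All figures are SVG, generated with matplotlib only, and are pure functions
of their inputs (fixed hash salt, no embedded date), so re-runs differ at
most in library-version details while glyph counts, colors, opacities and
track order are stable and asserted by XML parsing in the tests. Gene
glyphs carry `gene__*`/`track*_gene__*` group ids, homology rails
`rail__*`, heatmap cells `cell__*`. Colors: required purple `#800080`,
optional orange `#FFA500`, other genes green `#008000`, contig-edge
outline red `#FF0000`; fill opacity equals conservation (0 → fully
transparent, 1 → fully opaque; at opacity 0 the renderer elides the
outline too). Neighborhood panels place the focal window on top and the
rest in descending score order; rails run between adjacent tracks from
alignment coordinates mapped into gene spans (clamped to protein lengths),
all passing hits for non-modular genes, only the best-bit-score hit for
modular genes. Heatmap cells are individual vector rectangles on a linear
0→1 color scale — appropriate at desk scale; very large matrices would
want a rasterized mesh instead.

## Synthetic data

The generator plants one cluster template (required R1…, optional O1…,
filler F1… genes; 80-aa proteins; inter-gene gaps uniform in [200, 2000]
bp, drawn once so exact copies share their geometry) into each genome,
with per-genome variations: gene dropouts, substitution-mutated variants
at a controlled identity (verified within ±2 points), decoy genomes whose
cluster lacks a required gene, and contig-start truncations that trigger
the 500 bp edge flag. Background genes are unique per genome and kept ≥12
kb away from the cluster so the default 10 kb extension never pulls them
in and exact copies stay exactly identical at window level. DNA is random
with genes back-translated through a fixed codon table; everything is
byte-identical under a fixed seed. The generator does not model codon
usage, GC content, pseudogenes, assembly gaps or annotation errors — so
passing tests demonstrate algorithmic correctness on clean inputs, not
robustness to noisy real-world annotation.

Default study conditions used by the acceptance script: 7 genomes — five
exact copies, one optional-gene dropout, one decoy — 3 required + 2
optional + 3 filler genes. These sizes exercise every code path
(calling, rejection, deduplication, partial conservation) while keeping
the all-vs-all alignment stage to a few seconds on one CPU; the test
suite uses the same or smaller sizes throughout.

## Numerical choices and degenerate inputs

* Dedup identity tolerance 1e-9 absorbs float summation order.
* Percentiles (distance estimator, entropy quartiles) use numpy's linear
  interpolation.
* Zero-anchor windows cannot be scored and raise; zero windows is a clean
  "no windows" result, not an error.
* Dedup ties in length break lexicographically by window id; query-claim
  ties break by bit score then query id — all orderings are total, so
  identical inputs give byte-identical outputs.
* Window GenBank files embed real DNA when the contig sequence is
  available and an N-run otherwise; translations are always embedded so
  round-trip parsing never re-translates.

## Known limitations

* The built-in aligner is O(N²) in protein count; large genome sets
  require external DIAMOND/BLAST hits supplied as tabular files.
* Modular-query matching by category (not alignment) means a single
  planted hybrid in the database matches every modular query of
  compatible class; that is by design but can over-retrieve in
  category-rich databases.
* One-directional deduplication treats a shorter window identical near
  its anchors as a duplicate of a longer focal window even if the longer
  one carries extra genes; use `mutual` mode when strict content equality
  is wanted.
* No gene prediction: inputs must already contain CDS features with
  coordinates.
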