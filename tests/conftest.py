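"""Shared fixtures: in-memory genomes, planted datasets, and a full
pipeline run reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from gatorgc import pipeline, synthetic
from gatorgc.records import Contig, GeneRecord, make_gene_id
from gatorgc.windows import GatorWindow, HitAssignment


def make_contig(spans, genome="g1", contig="c1", length=None, strand=1,
                proteins=None):
    """Build a Contig from (start, end) spans with dummy proteins."""
    genes = []
    for i, (start, end) in enumerate(spans):
        seq = proteins[i] if proteins else "M" + "A" * max(1, (end - start) // 3 - 2)
        genes.append(GeneRecord(
            gene_id=make_gene_id(genome, contig, start, end, strand),
            contig_id=contig, start=start, end=end, strand=strand,
            locus_tag=f"{genome}_{i:03d}", product=f"protein {i}",
            protein_seq=seq))
    if length is None:
        length = max(e for _, e in spans) + 1000
    c = Contig(contig_id=contig, length=length, genome_id=genome, genes=genes)
    c.sort_genes()
    return c


def make_window(n_genes, anchor_indices, window_id=None, genome="g1",
                gene_len=300, gap=500, proteins=None):
    """An annotated in-memory window with anchors at the given ordinals."""
    if window_id is None:
        window_id = f"{genome}|c1|w001"
    spans = [(i * (gene_len + gap), i * (gene_len + gap) + gene_len)
             for i in range(n_genes)]
    contig = make_contig(spans, genome=genome, proteins=proteins)
    w = GatorWindow(window_id=window_id, genome_id=genome, contig_id="c1",
                    span_start=0, span_end=spans[-1][1] + 100,
                    genes=contig.genes)
    for k, i in enumerate(anchor_indices):
        w.hit_assignments[contig.genes[i].gene_id] = HitAssignment(
            f"q{k + 1}", "required")
    return w


def brute_force_required_clusters(contig, hit_dictionary, required_ids, cutoff):
    """Independent window oracle: connected components of the pairwise
    gap graph over required-hit genes, filtered for full required
    coverage. Returns a set of (core_start, core_end) spans."""
    req = set(required_ids)
    hit_by_gene = {}
    for q in req:
        for gid in hit_dictionary.get(q, set()):
            hit_by_gene.setdefault(gid, set()).add(q)
    genes = [g for g in contig.genes if g.gene_id in hit_by_gene]
    n = len(genes)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and genes[i].distance_to(genes[j]) <= cutoff:
                adj[i][j] = True
    seen, spans = set(), set()
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], []
        seen.add(s)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if adj[u][v] and v not in seen:
                    seen.add(v)
                    stack.append(v)
        covered = set().union(*(hit_by_gene[genes[i].gene_id] for i in comp))
        if req <= covered:
            spans.add((min(genes[i].start for i in comp),
                       max(genes[i].end for i in comp)))
    return spans


@pytest.fixture(scope="session")
def dataset7(tmp_path_factory):
    """Seven genomes: five exact cluster copies, one optional-gene dropout,
    one decoy missing a required gene."""
    spec = synthetic.PlantSpec(seed=1, n_genomes=7,
                               dropouts={5: ["O2"]}, decoy_genomes=[6])
    return synthetic.generate(spec, tmp_path_factory.mktemp("fixture7"))


@pytest.fixture(scope="session")
def mine7(dataset7, tmp_path_factory):
    """Full pipeline run (figures included) on the seven-genome fixture."""
    out = tmp_path_factory.mktemp("mine7")
    config = pipeline.RunConfig(
        genome_paths=[str(p) for p in dataset7.genome_paths],
        required_fasta=str(dataset7.required_fasta),
        optional_fasta=str(dataset7.optional_fasta),
        taxonomy_tsv=str(dataset7.taxonomy_path),
        out_dir=str(out))
    return pipeline.mine(config)
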