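"""Window calling: distance estimation, clustering rules, and the
brute-force oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from gatorgc.homology import ModularCategory
from gatorgc.windows import (WindowParams, annotate_window, call_windows,
                             estimate_default_distance)

from conftest import brute_force_required_clusters, make_contig


def _percentile_oracle(values, p):
    """Sorted-array linear-interpolation percentile, written independently."""
    xs = sorted(values)
    h = (len(xs) - 1) * p / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestEstimateDefaultDistance:
    def test_interpolation_on_arithmetic_pool(self):
        # one cluster of back-to-back genes gives consecutive-pair gaps
        # 0,10,...,990 plus larger multi-gene gaps; use single-pair clusters
        # to control the pool exactly: {0, 10, ..., 990}
        clusters = [[(0, 100), (100 + gap, 200 + gap)] for gap in range(0, 1000, 10)]
        assert estimate_default_distance(clusters, 95) == pytest.approx(940.5)

    def test_constant_distances(self):
        clusters = [[(0, 50), (100, 150)] for _ in range(7)]  # all gaps 50
        assert estimate_default_distance(clusters, 95) == pytest.approx(50.0)

    def test_overlapping_genes_distance_zero(self):
        clusters = [[(0, 200), (100, 300)]]
        assert estimate_default_distance(clusters, 50) == 0.0

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError):
            estimate_default_distance([[(0, 10)]])

    def test_random_pools_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            starts = np.sort(rng.integers(0, 100_000, size=n))
            spans = [(int(s), int(s) + int(rng.integers(100, 3000))) for s in starts]
            pool = [max(0, spans[j][0] - spans[i][1])
                    for i in range(n) for j in range(i + 1, n)]
            p = float(rng.uniform(1, 99))
            assert estimate_default_distance([spans], p) == pytest.approx(
                _percentile_oracle(pool, p), rel=1e-9)


def _hits(contig, assignment):
    """assignment: query -> list of gene ordinals."""
    return {q: {contig.genes[i].gene_id for i in idx}
            for q, idx in assignment.items()}


class TestCallWindows:
    def test_two_required_within_cutoff(self):
        contig = make_contig([(10_000, 11_000), (50_000, 51_000)], length=200_000)
        hits = _hits(contig, {"qA": [0], "qB": [1]})
        windows = call_windows([contig], hits, ["qA", "qB"])
        assert len(windows) == 1
        w = windows[0]
        assert w.span_start == 0  # 10 kb flank clamped at the contig start
        assert w.span_end == 61_000
        assert set(w.hit_assignments) == {g.gene_id for g in contig.genes}

    def test_gap_beyond_cutoff_no_window(self):
        contig = make_contig([(0, 1000), (91_000, 92_000)], length=200_000)
        hits = _hits(contig, {"qA": [0], "qB": [1]})
        assert call_windows([contig], hits, ["qA", "qB"]) == []

    def test_required_on_different_contigs_no_window(self):
        c1 = make_contig([(0, 1000)], contig="c1")
        c2 = make_contig([(0, 1000)], contig="c2")
        hits = {"qA": {c1.genes[0].gene_id}, "qB": {c2.genes[0].gene_id}}
        assert call_windows([c1, c2], hits, ["qA", "qB"]) == []

    def test_flank_genes_included_and_extension_count_invariance(self):
        spans = [(1000, 1500), (20_000, 20_500), (24_000, 24_500),
                 (31_000, 31_500), (60_000, 60_500)]
        contig = make_contig(spans, length=100_000)
        hits = _hits(contig, {"qA": [1], "qB": [3]})
        params0 = WindowParams(required_distance=20_000, window_extension=0)
        params10 = WindowParams(required_distance=20_000, window_extension=10_000)
        w0 = call_windows([contig], hits, ["qA", "qB"], params=params0)
        w10 = call_windows([contig], hits, ["qA", "qB"], params=params10)
        assert len(w0) == len(w10) == 1
        assert [g.gene_id for g in w0[0].genes] == [contig.genes[i].gene_id
                                                    for i in (1, 2, 3)]
        # 10 kb extension picks up the 1 kb-side flank gene, not the 60 kb one
        assert [g.gene_id for g in w10[0].genes] == [contig.genes[i].gene_id
                                                     for i in (1, 2, 3)]
        assert w10[0].span_start == 10_000
        assert w10[0].span_end == 41_500

    def test_monotone_in_distance_cutoff(self):
        rng = np.random.default_rng(7)
        starts = np.cumsum(rng.integers(500, 15_000, size=20))
        contig = make_contig([(int(s), int(s) + 600) for s in starts],
                             length=int(starts[-1]) + 20_000)
        hits = _hits(contig, {"qA": [0, 5, 9, 14], "qB": [2, 6, 11, 19]})
        covered = {}
        for cutoff in (2_000, 8_000, 20_000, 80_000):
            ws = call_windows([contig], hits, ["qA", "qB"],
                              params=WindowParams(required_distance=cutoff,
                                                  window_extension=0))
            covered[cutoff] = set().union(*(set(w.gene_ids) for w in ws)) if ws else set()
        assert covered[2_000] <= covered[8_000] <= covered[20_000] <= covered[80_000]

    def test_determinism(self):
        contig = make_contig([(0, 1000), (5000, 6000)], length=50_000)
        hits = _hits(contig, {"qA": [0], "qB": [1]})
        a = call_windows([contig], hits, ["qA", "qB"])
        b = call_windows([contig], hits, ["qA", "qB"])
        assert [w.window_id for w in a] == [w.window_id for w in b]
        assert [w.gene_ids for w in a] == [w.gene_ids for w in b]

    def test_oracle_equivalence_random_genomes(self):
        """Single-linkage chaining equals connected components of the
        pairwise gap graph on 50 random genomes."""
        rng = np.random.default_rng(123)
        required = ["qA", "qB", "qC"]
        for trial in range(50):
            n = int(rng.integers(10, 80))
            starts = np.cumsum(rng.integers(200, 9000, size=n))
            spans = [(int(s), int(s) + int(rng.integers(300, 3000))) for s in starts]
            contig = make_contig(spans, genome=f"g{trial}",
                                 length=spans[-1][1] + 5000)
            hits = {q: {g.gene_id for g in contig.genes if rng.random() < 0.12}
                    for q in required}
            cutoff = int(rng.integers(2000, 30_000))
            ws = call_windows([contig], hits, required,
                              params=WindowParams(required_distance=cutoff,
                                                  window_extension=0),
                              merge_overlapping=False)
            got = set()
            for w in ws:
                req_genes = [g for g in w.genes
                             if any(g.gene_id in hits[q] for q in required)]
                got.add((min(g.start for g in req_genes),
                         max(g.end for g in req_genes)))
            expected = brute_force_required_clusters(contig, hits, required, cutoff)
            assert got == expected, f"trial {trial}"

    def test_complete_linkage_stricter(self):
        # three genes in a chain: adjacent gaps 10 kb, end-to-end 20 kb+
        contig = make_contig([(0, 1000), (11_000, 12_000), (22_000, 23_000)],
                             length=60_000)
        hits = _hits(contig, {"qA": [0, 1], "qB": [2]})
        params = WindowParams(required_distance=15_000, window_extension=0)
        single = call_windows([contig], hits, ["qA", "qB"], params=params,
                              linkage="single")
        complete = call_windows([contig], hits, ["qA", "qB"], params=params,
                                linkage="complete")
        assert len(single) == 1
        assert complete == []

    def test_overlapping_windows_merge_toggle(self):
        # two required pairs whose extended spans overlap
        contig = make_contig([(0, 1000), (3000, 4000),
                              (30_000, 31_000), (33_000, 34_000)],
                             length=100_000)
        hits = {"qA": {contig.genes[0].gene_id, contig.genes[2].gene_id},
                "qB": {contig.genes[1].gene_id, contig.genes[3].gene_id}}
        params = WindowParams(required_distance=10_000, window_extension=20_000)
        merged = call_windows([contig], hits, ["qA", "qB"], params=params)
        split = call_windows([contig], hits, ["qA", "qB"], params=params,
                             merge_overlapping=False)
        assert len(merged) == 1 and len(split) == 2


class TestAnnotateWindow:
    def test_roles_categories_and_precedence(self):
        contig = make_contig([(0, 1000), (2000, 3000), (4000, 5000)],
                             length=20_000)
        hits = {"req1": {contig.genes[0].gene_id, contig.genes[1].gene_id},
                "opt1": {contig.genes[1].gene_id, contig.genes[2].gene_id}}
        cats = {contig.genes[2].gene_id: ModularCategory.HYBRID}
        ws = call_windows([contig], hits, ["req1"], ["opt1"],
                          params=WindowParams(window_extension=2_000),
                          categories=cats)
        w = ws[0]
        a = w.hit_assignments
        assert a[contig.genes[0].gene_id].role == "required"
        # gene hit by both a required and an optional query: required wins
        assert a[contig.genes[1].gene_id] == \
            a[contig.genes[0].gene_id].__class__("req1", "required")
        assert a[contig.genes[2].gene_id].role == "optional"
        assert w.categories[contig.genes[2].gene_id].is_nrps
        assert w.categories[contig.genes[2].gene_id].is_pks

    def test_tie_break_by_bit_score(self):
        contig = make_contig([(0, 1000)], length=10_000)
        gid = contig.genes[0].gene_id
        hits = {"optA": {gid}, "optB": {gid}}
        ws = call_windows([contig], hits, ["optA"], [],
                          params=WindowParams(window_extension=0))
        w = ws[0]
        annotate_window(w, hits, [], ["optA", "optB"],
                        scores={("optB", gid): 300.0, ("optA", gid): 120.0})
        assert w.hit_assignments[gid].query_id == "optB"
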