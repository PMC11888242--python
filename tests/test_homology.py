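"""Hit filtering, the built-in aligner oracle, and modular classification."""

from __future__ import annotations

import itertools

import pytest

from gatorgc import homology
from gatorgc.homology import (DomainHit, ModularCategory, MotifDomainSource,
                              QueryProtein, builtin_search, build_hit_dictionary,
                              classify_modularity, load_domain_hits,
                              load_tabular_hits, screen_queries,
                              write_tabular_hits)
from gatorgc.synthetic import random_protein
import numpy as np


def _row(qid="q", sid="s", pid=90.0, qstart=1, qend=100, qcov=None):
    cols = [qid, sid, f"{pid}", str(qend - qstart + 1), "0", "0",
            str(qstart), str(qend), "1", str(qend - qstart + 1), "1e-30", "200"]
    if qcov is not None:
        cols.append(str(qcov))
    return "\t".join(cols)


class TestLoadTabular:
    def test_threshold_filtering(self, tmp_path):
        # 10 rows, 4 below the default 35% identity / 70% coverage cutoffs
        rows = [
            _row(pid=34.9, qcov=80),   # fails identity
            _row(pid=35.0, qcov=69.9),  # fails coverage
            _row(pid=20.0, qcov=20.0),  # fails both
            _row(pid=34.99, qcov=100),  # fails identity
            _row(pid=100, qcov=100),    # self-hit style, passes
            _row(pid=35.0, qcov=70.0),  # exactly at both thresholds, passes
            _row(pid=50, qcov=75),
            _row(pid=99, qcov=71),
            _row(pid=36, qcov=99),
            _row(pid=80, qcov=80),
        ]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(rows) + "\n")
        hits = load_tabular_hits(path)
        assert len(hits) == 6
        assert all(h.pct_identity >= 35 and h.query_cover >= 70 for h in hits)

    def test_coverage_derived_from_query_length(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_row(qid="qA", qstart=1, qend=80) + "\n")
        hits = load_tabular_hits(path, query_lengths={"qA": 100})
        assert hits and hits[0].query_cover == pytest.approx(80.0)
        with pytest.raises(ValueError):
            load_tabular_hits(path)  # no coverage column, no lengths

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("only\tthree\tcols\n" + _row(qcov=90) + "\n")
        assert len(load_tabular_hits(path)) == 1

    def test_filter_monotonicity(self, tmp_path):
        rows = [_row(pid=float(p), qcov=float(c))
                for p in (30, 40, 60, 90) for c in (50, 72, 95)]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(rows) + "\n")
        base = len(load_tabular_hits(path, min_qcov=70, min_pid=35))
        assert len(load_tabular_hits(path, min_qcov=70, min_pid=50)) <= base
        assert len(load_tabular_hits(path, min_qcov=90, min_pid=35)) <= base


def _domrow(protein, profile, evalue, env=(5, 60)):
    # domtblout layout: target name ... profile(col4) ... i-evalue(col13)
    # score(col14) ... env bounds (cols 20-21)
    cols = [protein, "-", "400", profile, "-", "120"] + ["0"] * 6
    cols += [f"{evalue}", "55.0"] + ["0"] * 5 + [str(env[0]), str(env[1]), "0.9"]
    return " ".join(cols)


class TestLoadDomainHits:
    def test_evalue_filter_and_mapping(self, tmp_path):
        rows = [
            _domrow("p1", "AMP-binding", 1e-3),   # above threshold, dropped
            _domrow("p1", "AMP-binding", 0.0),    # boundary best case, kept
            _domrow("p2", "Condensation", 1e-9),
            _domrow("p3", "UnknownProfile", 1e-9),  # unmapped, ignored
            _domrow("p3", "PKS_AT", 1e-5),
        ]
        path = tmp_path / "dom.tsv"
        path.write_text("# comment\n" + "\n".join(rows) + "\n")
        hits = load_domain_hits(path)
        assert [(h.protein_id, h.domain) for h in hits] == [
            ("p1", "A"), ("p2", "C"), ("p3", "AT")]

    def test_fixture_counts(self, tmp_path):
        rows = [_domrow(f"a{i}", "AMP-binding", 1e-8) for i in range(3)]
        rows += [_domrow(f"c{i}", "Condensation", 1e-8) for i in range(2)]
        rows += [_domrow("t1", "PKS_AT", 1e-8)]
        path = tmp_path / "dom.tsv"
        path.write_text("\n".join(rows) + "\n")
        assert len(load_domain_hits(path)) == 6


class TestBuiltinSearch:
    def test_self_hit_identity(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 120)
        hits = builtin_search([("q", seq)], [("s", seq)])
        assert len(hits) == 1
        h = hits[0]
        assert h.pct_identity == pytest.approx(100.0)
        assert h.query_cover == pytest.approx(100.0)
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 120, 1, 120)

    def test_no_shared_signal_no_hit(self):
        hits = builtin_search([("q", "W" * 50)], [("s", "P" * 50)])
        assert hits == []

    def test_query_equals_first_half_of_subject(self):
        rng = np.random.default_rng(1)
        subject = random_protein(rng, 200)
        query = subject[:100]
        hits = builtin_search([("q", query)], [("s", subject)])
        assert len(hits) == 1
        h = hits[0]
        assert h.pct_identity == pytest.approx(100.0)
        assert h.query_cover == pytest.approx(100.0)
        assert (h.s_start, h.s_end) == (1, 100)

    def test_db_self_consistency(self):
        rng = np.random.default_rng(2)
        db = [(f"p{i}", random_protein(rng, 60 + 10 * i)) for i in range(5)]
        hits = builtin_search(db, db)
        self_hits = {h.query_id for h in hits
                     if h.query_id == h.subject_id
                     and h.pct_identity == 100.0 and h.query_cover == 100.0}
        assert self_hits == {f"p{i}" for i in range(5)}

    def test_tabular_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        seqs = [(f"p{i}", random_protein(rng, 90)) for i in range(3)]
        hits = builtin_search(seqs, seqs)
        path = tmp_path / "hits.tsv"
        write_tabular_hits(hits, path)
        back = load_tabular_hits(path)
        assert {(h.query_id, h.subject_id) for h in back} == \
               {(h.query_id, h.subject_id) for h in hits}
        for a, b in zip(sorted(hits, key=lambda h: (h.query_id, h.subject_id)),
                        sorted(back, key=lambda h: (h.query_id, h.subject_id))):
            assert a.pct_identity == pytest.approx(b.pct_identity, abs=0.01)
            assert a.query_cover == pytest.approx(b.query_cover, abs=0.01)

    def test_raising_thresholds_never_adds_hits(self):
        rng = np.random.default_rng(4)
        base_seq = random_protein(rng, 100)
        variants = [("v1", base_seq),
                    ("v2", base_seq[:50] + random_protein(rng, 50)),
                    ("v3", random_protein(rng, 100))]
        loose = builtin_search([("q", base_seq)], variants, min_qcov=30, min_pid=20)
        tight = builtin_search([("q", base_seq)], variants, min_qcov=70, min_pid=35)
        loose_pairs = {(h.query_id, h.subject_id) for h in loose}
        tight_pairs = {(h.query_id, h.subject_id) for h in tight}
        assert tight_pairs <= loose_pairs


class TestClassifyModularity:
    RULES = {  # independent statement of the three rules
        frozenset(s): cat for s, cat in [
            (("A", "C"), ModularCategory.NRPS),
            (("AT", "KS"), ModularCategory.PKS),
        ]
    }

    def _expected(self, subset):
        nrps = {"A", "C"} <= subset
        pks = {"AT", "KS"} <= subset
        if nrps and pks:
            return ModularCategory.HYBRID
        if nrps:
            return ModularCategory.NRPS
        if pks:
            return ModularCategory.PKS
        return ModularCategory.NONE

    @pytest.mark.parametrize("subset", [
        set(c) for r in range(5) for c in itertools.combinations(
            ("A", "C", "AT", "KS"), r)
    ], ids=lambda s: "+".join(sorted(s)) or "none")
    def test_all_16_subsets(self, subset):
        assert classify_modularity(subset) == self._expected(subset)

    def test_order_independent_and_idempotent(self):
        hits = [DomainHit("p", d, 1e-9, 1, 50) for d in ("C", "A", "A")]
        assert classify_modularity(hits) == ModularCategory.NRPS
        assert classify_modularity(reversed(hits)) == ModularCategory.NRPS


class TestScreenAndDictionary:
    def _queries(self):
        return [
            QueryProtein("nrpsQ", "M" * 20 + "WCWCWCAD" + "WCWCWCCD" + "M" * 20, "required"),
            QueryProtein("pksQ", "M" * 20 + "WCWCWCAT" + "WCWCWCKS" + "M" * 20, "required"),
            QueryProtein("plain1", "M" * 60, "required"),
            QueryProtein("plain2", "K" * 60, "optional"),
        ]

    def test_partition(self):
        modular, plain = screen_queries(self._queries(), MotifDomainSource())
        assert {q.query_id for q in modular} == {"nrpsQ", "pksQ"}
        assert {q.query_id for q in plain} == {"plain1", "plain2"}
        assert modular[0].category == ModularCategory.NRPS
        assert modular[1].category == ModularCategory.PKS

    def test_hit_dictionary_modular_matching(self):
        queries = self._queries()
        screen_queries(queries, MotifDomainSource())
        db_cats = {"g_nrps1": ModularCategory.NRPS,
                   "g_nrps2": ModularCategory.NRPS,
                   "g_nrps3": ModularCategory.NRPS,
                   "g_pks1": ModularCategory.PKS,
                   "g_pks2": ModularCategory.PKS,
                   "g_hyb": ModularCategory.HYBRID,
                   "g_plain": ModularCategory.NONE}
        hits = [homology.HomologyHit("plain1", "g_plain", 90, 95, 1e-40, 100, 1, 50, 1, 50)]
        d = build_hit_dictionary(queries, hits, db_cats)
        assert d["nrpsQ"] == {"g_nrps1", "g_nrps2", "g_nrps3", "g_hyb"}
        assert d["pksQ"] == {"g_pks1", "g_pks2", "g_hyb"}
        assert d["plain1"] == {"g_plain"}
        assert d["plain2"] == set()

    def test_hybrid_query_strict_matching(self):
        q = QueryProtein("hyb", "WCWCWCADWCWCWCCDWCWCWCATWCWCWCKS" + "M" * 30,
                         "required")
        screen_queries([q], MotifDomainSource())
        assert q.category == ModularCategory.HYBRID
        db_cats = {"g_hyb": ModularCategory.HYBRID,
                   "g_nrps1": ModularCategory.NRPS,
                   "g_nrps2": ModularCategory.NRPS}
        d = build_hit_dictionary([q], [], db_cats)
        assert d["hyb"] == {"g_hyb"}
        d_strict = build_hit_dictionary([q], [], db_cats, strict_modular=True)
        assert d_strict["hyb"] == {"g_hyb"}
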