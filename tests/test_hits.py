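"""Hit-table parsing, normalization, and the retention rules."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alienscreen.errors import HitParseError, NormalizationError
from alienscreen.hits import (
    apply_length_filter,
    normalize,
    parse_hits,
    read_self_scores,
    select_tree_set,
    sort_and_cap,
)

from conftest import make_table

TAXON_MAP = {"t1": 435, "t2": 436, "q1": 1003835}


def tblout_line(target, query, evalue, full, dom):
    rest = "0.1 1.1 1 0 0 1 1 1 1 -"
    return f"{target} - {query} - {evalue} {full} 0.1 {evalue} {dom} {rest}"


def domtblout_line(target, query, evalue, full, dom_score, dom_i=1, dom_n=1):
    return (f"{target} - 400 {query} - 380 {evalue} {full} 0.1 {dom_i} {dom_n} "
            f"{evalue} {evalue} {dom_score} 0.1 1 100 1 100 1 100 0.9 -")


class TestParsing:
    def test_tblout_two_targets_one_query(self):
        text = "\n".join([
            "# comment line",
            tblout_line("t1", "q1", "1e-50", 170.0, 165.0),
            tblout_line("t2", "q1", "1e-20", 80.0, 78.0),
        ])
        tables = parse_hits(io.StringIO(text), dialect="hmmer_tblout", taxon_map=TAXON_MAP)
        assert len(tables) == 1
        t = tables[0]
        assert [h.target_id for h in t.hits] == ["t1", "t2"]
        assert t.hits[0].full_bitscore == 170.0
        assert t.hits[0].best_domain_bitscore == 165.0
        assert t.hits[1].evalue == 1e-20

    def test_domtblout_best_domain_is_max_over_rows(self):
        """A target with domains at 80 and 120 bits gets best-domain 120."""
        text = "\n".join([
            domtblout_line("t1", "q1", "1e-40", 150.0, 80.0, dom_i=1, dom_n=2),
            domtblout_line("t1", "q1", "1e-40", 150.0, 120.0, dom_i=2, dom_n=2),
        ])
        tables = parse_hits(io.StringIO(text), dialect="hmmer_domtblout", taxon_map=TAXON_MAP)
        (hit,) = tables[0].hits
        assert hit.best_domain_bitscore == 120.0
        assert hit.full_bitscore == 150.0

    def test_non_numeric_bitscore_reports_line(self):
        text = "\n".join([
            tblout_line("t1", "q1", "1e-50", 170.0, 165.0),
            tblout_line("t2", "q1", "1e-20", "oops", 78.0),
        ])
        with pytest.raises(HitParseError, match="line 2"):
            parse_hits(io.StringIO(text), dialect="hmmer_tblout", taxon_map=TAXON_MAP)

    def test_generic_tsv_and_duplicate_rows(self, caplog):
        text = ("query\ttarget\ttaxid\tbitscore\tdom_bitscore\tevalue\n"
                "q1\tt1\t435\t100\t95\t1e-20\n"
                "q1\tt1\t435\t130\t125\t1e-25\n")
        with caplog.at_level("WARNING"):
            tables = parse_hits(io.StringIO(text), dialect="generic_tsv")
        (hit,) = tables[0].hits
        assert hit.full_bitscore == 130.0
        assert "duplicate" in caplog.text

    def test_uncovered_target_tolerated(self, caplog):
        text = tblout_line("unknown_target", "q1", "1e-50", 170.0, 165.0)
        with caplog.at_level("WARNING"):
            tables = parse_hits(io.StringIO(text), dialect="hmmer_tblout", taxon_map=TAXON_MAP)
        assert tables[0].hits[0].taxid == -1

    def test_self_score_sidecar(self):
        scores = read_self_scores(io.StringIO("q1\t200.5\nq2\t310\n"))
        assert scores == {"q1": 200.5, "q2": 310.0}


class TestNormalize:
    def test_quotient(self):
        t = normalize(make_table(self_score=200, hits=[("t1", 435, 150.0)]))
        assert t.hits[0].nbs == pytest.approx(0.75)

    def test_self_hit_is_one_and_supplies_score(self):
        t = make_table(self_score=None, hits=[("q1", 1003835, 200.0), ("t1", 435, 50.0)])
        t = normalize(t)
        assert t.self_score == 200.0
        assert t.hits[0].nbs == 1.0
        assert t.hits[1].nbs == pytest.approx(0.25)

    def test_zero_bitscore_gives_zero(self):
        t = normalize(make_table(self_score=200, hits=[("t1", 435, 0.0)]))
        assert t.hits[0].nbs == 0.0

    def test_missing_self_score_raises(self):
        with pytest.raises(NormalizationError, match="q1"):
            normalize(make_table(self_score=None, hits=[("t1", 435, 50.0)]))

    def test_overshoot_clamped_and_counted(self):
        t = normalize(make_table(self_score=100, hits=[("t1", 435, 150.0)]))
        assert t.hits[0].nbs == 1.0
        assert t.n_clamped == 1
        # overshoot within tolerance clamps silently
        t2 = normalize(make_table(self_score=100, hits=[("t1", 435, 100.0 + 5e-8)]))
        assert t2.hits[0].nbs == 1.0
        assert t2.n_clamped == 0


def brute_force_cap(hits, max_total, max_per_taxon):
    """Independent retention oracle: per-taxid top-k under the total order,
    then a global truncation of the merged, re-sorted survivors."""
    key = lambda h: (-h.nbs, h.evalue, h.target_id)
    survivors = []
    by_taxid = {}
    for h in hits:
        by_taxid.setdefault(h.taxid, []).append(h)
    for hs in by_taxid.values():
        survivors.extend(sorted(hs, key=key)[:max_per_taxon])
    return sorted(survivors, key=key)[:max_total]


class TestSortAndCap:
    def test_per_taxon_cap_keeps_top_five(self):
        hits = [(f"t{i:02d}", 435, float(10 + i)) for i in range(20)]
        t = sort_and_cap(normalize(make_table(self_score=100, hits=hits)))
        assert len(t.hits) == 5
        assert [h.best_domain_bitscore for h in t.hits] == [29.0, 28.0, 27.0, 26.0, 25.0]

    def test_global_cap(self):
        hits = [(f"t{i:05d}", 10_000 + i, float(i % 97) + 1) for i in range(15_000)]
        t = sort_and_cap(normalize(make_table(self_score=100, hits=hits)))
        assert len(t.hits) == 10_000

    def test_empty_table_passes_through(self):
        t = sort_and_cap(normalize(make_table(self_score=100, hits=[("t1", 1, 1.0)])))
        t.hits.clear()
        assert sort_and_cap(t).hits == []

    def test_deterministic_tie_order(self):
        hits = [("b", 435, 50.0, 1e-10), ("a", 436, 50.0, 1e-10), ("c", 437, 50.0, 1e-10)]
        t = sort_and_cap(normalize(make_table(self_score=100, hits=hits)))
        assert [h.target_id for h in t.hits] == ["a", "b", "c"]

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 120), st.integers(1, 8))
    def test_matches_oracle_and_idempotent(self, seed, n, n_taxa):
        rng = random.Random(seed)
        hits = [(f"t{i:03d}", rng.randrange(n_taxa), float(rng.randrange(200)),
                 10.0 ** -rng.randrange(60)) for i in range(n)]
        t = normalize(make_table(self_score=250, hits=hits))
        capped = sort_and_cap(t, max_total=30, max_per_taxon=5)
        expect = brute_force_cap(t.hits, 30, 5)
        assert [h.target_id for h in capped.hits] == [h.target_id for h in expect]
        again = sort_and_cap(capped, max_total=30, max_per_taxon=5)
        assert [h.target_id for h in again.hits] == [h.target_id for h in capped.hits]
        assert all(h.nbs is not None and 0 <= h.nbs <= 1 for h in capped.hits)


class TestTreeSetSelection:
    def make(self, n, evalue):
        hits = [(f"t{i:04d}", i, 50.0, evalue) for i in range(n)]
        return sort_and_cap(normalize(make_table(self_score=100, hits=hits)))

    def test_caps_at_200(self):
        sel = select_tree_set(self.make(500, 1e-30))
        assert len(sel.selected_target_ids) == 200

    def test_fewer_than_cap(self):
        sel = select_tree_set(self.make(50, 1e-30))
        assert len(sel.selected_target_ids) == 50

    def test_cutoff_is_strict(self):
        """E-values at or above 1e-10 never qualify (strict <)."""
        assert select_tree_set(self.make(10, 1e-9)).selected_target_ids == []
        assert select_tree_set(self.make(10, 1e-10)).selected_target_ids == []
        assert len(select_tree_set(self.make(10, 9.9e-11)).selected_target_ids) == 10

    def test_selection_preserves_table_order(self):
        hits = [("b", 1, 80.0, 1e-30), ("a", 2, 90.0, 1e-30), ("c", 3, 70.0, 1e-30)]
        t = sort_and_cap(normalize(make_table(self_score=100, hits=hits)))
        assert select_tree_set(t).selected_target_ids == ["a", "b", "c"]


class TestLengthFilter:
    def test_boundary(self):
        assert apply_length_filter({"a": 149, "b": 150, "c": 151}) == {"b", "c"}

    def test_empty(self):
        assert apply_length_filter({}) == set()

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            apply_length_filter({"a": -1})
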