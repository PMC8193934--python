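import numpy as np
import pytest
from hypothesis import given, strategies as st

from netpharm.enrichment import bh_adjust, enrich, hypergeom_upper_tail
from netpharm.errors import EmptyResultError, ValidationError
from netpharm.geneset_ops import GeneSet
from netpharm.io_formats import AnnotationSet, AnnotationTerm
from netpharm.synthetic_data import gen_annotations

from oracles import bh_oracle, hypergeom_comb, hypergeom_enum


class TestHypergeomUpperTail:
    def test_worked_case(self):
        # draw 4 of 10, 5 marked: P(X >= 4) = C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_degenerate_certainty(self):
        assert hypergeom_upper_tail(6, 6, 6, 6) == 1.0

    def test_matches_literal_draw_enumeration(self):
        for n_universe in range(1, 11):
            for marked in range(n_universe + 1):
                for drawn in range(n_universe + 1):
                    for k in range(min(marked, drawn) + 1):
                        expected = hypergeom_enum(k, marked, drawn, n_universe)
                        got = hypergeom_upper_tail(k, marked, drawn, n_universe)
                        assert got == pytest.approx(expected, abs=1e-10)

    def test_counting_oracle_larger_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            big_n = int(rng.integers(1, 21))
            big_k = int(rng.integers(0, big_n + 1))
            n = int(rng.integers(0, big_n + 1))
            k = int(rng.integers(0, min(big_k, n) + 1))
            assert hypergeom_upper_tail(k, big_k, n, big_n) == pytest.approx(
                hypergeom_comb(k, big_k, n, big_n), abs=1e-10
            )

    def test_inconsistent_arguments_fatal(self):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(1, 11, 4, 10)
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(-1, 5, 4, 10)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_out_of_range_fatal(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_literal_step_up_and_dominates_p(self, pvalues):
        adjusted = bh_adjust(pvalues)
        expected = bh_oracle(pvalues)
        assert adjusted == pytest.approx(expected, abs=1e-12)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, pvalues))
        order = np.argsort(pvalues, kind="stable")
        ranked = [adjusted[i] for i in order]
        assert all(x <= y + 1e-12 for x, y in zip(ranked, ranked[1:]))


def _annotations(**terms):
    return AnnotationSet(terms={
        tid: AnnotationTerm(tid, tid, "BP", frozenset(members))
        for tid, members in terms.items()
    })


class TestEnrich:
    def test_term_identical_to_query(self):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(13)))
        query = GeneSet("q", frozenset({"G0", "G1", "G2"}))
        annotations = _annotations(T1={"G0", "G1", "G2"})
        rows = enrich(query, annotations, universe=universe)
        # overlap must be the full query: p = 1 / C(13, 3)
        assert rows[0].k == 3
        assert rows[0].p == pytest.approx(1 / 286)
        assert rows[0].padj == pytest.approx(rows[0].p)
        assert rows[0].significant

    def test_disjoint_term_not_significant(self):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(20)))
        query = GeneSet("q", frozenset({"G0", "G1"}))
        annotations = _annotations(T1={"G10", "G11"})
        rows = enrich(query, annotations, universe=universe)
        assert rows[0].k == 0
        assert rows[0].p == 1.0
        assert not rows[0].significant

    def test_empty_query_universe_overlap_fatal(self):
        universe = GeneSet("u", frozenset({"A", "B"}))
        query = GeneSet("q", frozenset({"X"}))
        with pytest.raises(EmptyResultError):
            enrich(query, _annotations(T1={"A"}), universe=universe)

    def test_namespaces_adjusted_separately_by_default(self):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(30)))
        terms = {
            f"B{i}": AnnotationTerm(f"B{i}", "x", "BP",
                                    frozenset({f"G{i}", f"G{i + 1}"}))
            for i in range(5)
        }
        terms["K1"] = AnnotationTerm("K1", "x", "KEGG",
                                     frozenset({"G0", "G1", "G2"}))
        annotations = AnnotationSet(terms=terms)
        query = GeneSet("q", frozenset({"G0", "G1", "G2"}))
        rows = enrich(query, annotations, universe=universe)
        kegg = [r for r in rows if r.namespace == "KEGG"]
        # single-term KEGG family: padj equals p
        assert kegg[0].padj == pytest.approx(kegg[0].p)

    def test_planted_term_ranks_first_across_replicates(self):
        universe = [f"G{i}" for i in range(200)]
        rng = np.random.default_rng(123)
        first = 0
        n_rep = 100
        for rep in range(n_rep):
            query = rng.choice(universe, size=25, replace=False).tolist()
            annotations, ledger = gen_annotations(
                query=query, universe=universe, n_terms=50, seed=rep
            )
            rows = enrich(
                GeneSet("q", frozenset(query)),
                annotations,
                universe=GeneSet("u", frozenset(universe)),
            )
            if rows[0].term_id == ledger.planted_term_id:
                first += 1
        assert first >= 95
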