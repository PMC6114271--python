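"""Hypergeometric over-representation, BH FDR, and kappa grouping."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet.enrichment import (
    bh_adjust,
    enrich_gene_sets,
    group_terms_by_kappa,
    hypergeometric_pvalue,
    kappa_score,
    significant_rows,
)
from herbnet.errors import ValidationError
from herbnet.io import GeneSetCollection
from herbnet.simulate import simulate_enrichment


def enumeration_pvalue(k, K, n, N):
    """Oracle: P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    population = range(N)
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_zero_overlap_upper_tail_is_one(self):
        assert hypergeometric_pvalue(0, 5, 4, 10) == 1.0

    @pytest.mark.parametrize(
        "k, K, n, N, expected",
        [
            (4, 5, 4, 10, 5 / 210),
            (2, 3, 3, 6, 10 / 20),
        ],
    )
    def test_hand_enumerated_values(self, k, K, n, N, expected):
        assert hypergeometric_pvalue(k, K, n, N) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_pvalue(5, 3, 4, 10)
        with pytest.raises(ValidationError):
            hypergeometric_pvalue(1, 11, 4, 10)

    def test_agrees_with_enumeration_oracle_on_small_lattice(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeometric_pvalue(k, K, n, N) == pytest.approx(
                            enumeration_pvalue(k, K, n, N)
                        ), (k, K, n, N)


class TestBhAdjust:
    def test_step_up_minima(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])

    @settings(derandomize=True, max_examples=100)
    @given(
        ps=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20),
        idx=st.integers(min_value=0, max_value=19),
        bump=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_increasing_a_pvalue_never_adds_discoveries(self, ps, idx, bump):
        idx %= len(ps)
        q_before = bh_adjust(ps)
        worse = list(ps)
        worse[idx] = min(1.0, worse[idx] + bump)
        q_after = bh_adjust(worse)
        n_disc = lambda qs: sum(q <= 0.05 for q in qs)
        assert n_disc(q_after) <= n_disc(q_before)

    def test_sorted_q_monotone_with_sorted_p(self):
        rng = np.random.default_rng(0)
        p = sorted(rng.uniform(1e-4, 1, 30))
        q = bh_adjust(p)
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(q, q[1:]))


def _collection():
    bg = {f"G{i}" for i in range(40)}
    return GeneSetCollection(
        background=frozenset(bg),
        terms={
            "T1": ("full hit", frozenset({"G0", "G1", "G2", "G3"})),
            "T2": ("partial", frozenset({"G2", "G3", "G4", "G5", "G6"})),
            "T3": ("miss", frozenset({f"G{i}" for i in range(20, 30)})),
        },
    )


class TestEnrich:
    def test_full_term_query_ranks_first(self):
        rows = enrich_gene_sets({"G0", "G1", "G2", "G3"}, _collection())
        assert rows[0].term_id == "T1"
        assert rows[0].k == 4 and rows[0].K == 4

    def test_query_outside_background_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="herbnet"):
            rows = enrich_gene_sets({"G0", "G1", "NOT_A_GENE"}, _collection())
        assert "dropped" in caplog.text
        assert rows[0].n == 2

    def test_empty_query_after_intersection_rejected(self):
        with pytest.raises(ValidationError):
            enrich_gene_sets({"NOPE"}, _collection())

    def test_term_size_window_applied_before_testing(self):
        rows = enrich_gene_sets({"G0", "G1"}, _collection(), min_term_size=5)
        assert {r.term_id for r in rows} == {"T2", "T3"}

    def test_planted_term_recovery_rate(self):
        ranks_first = 0
        n_rep = 50
        for rep in range(n_rep):
            query, coll, planted = simulate_enrichment(seed=1000 + rep)
            rows = enrich_gene_sets(query, coll)
            if rows[0].term_id == planted:
                ranks_first += 1
        assert ranks_first / n_rep >= 0.95


class TestKappa:
    def test_identical_terms_score_one(self):
        bg = {"G1", "G2", "G3", "G4"}
        assert kappa_score({"G1", "G2"}, {"G1", "G2"}, bg) == pytest.approx(1.0)

    def test_disjoint_terms_covering_background_negative(self):
        bg = {"G1", "G2", "G3", "G4"}
        assert kappa_score({"G1", "G2"}, {"G3", "G4"}, bg) < 0

    def test_hand_computed_value(self):
        bg = {f"G{i}" for i in range(1, 11)}
        k = kappa_score({"G1", "G2"}, {"G1", "G2", "G3"}, bg)
        assert k == pytest.approx((0.9 - 0.62) / (1 - 0.62))

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        bg = [f"G{i}" for i in range(30)]
        for _ in range(20):
            a = set(rng.choice(bg, rng.integers(1, 20), replace=False))
            b = set(rng.choice(bg, rng.integers(1, 20), replace=False))
            assert kappa_score(a, b, bg) == pytest.approx(kappa_score(b, a, bg))

    def test_degenerate_table_warns_and_returns_zero(self):
        bg = {"G1", "G2"}
        with pytest.warns(UserWarning):
            assert kappa_score(bg, bg, bg) == 0.0

    def test_term_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            kappa_score({"X"}, {"G1"}, {"G1"})


class TestGrouping:
    def _rows_and_collection(self, terms):
        bg = frozenset(f"G{i}" for i in range(1, 21))
        coll = GeneSetCollection(
            background=bg,
            terms={tid: (tid, frozenset(genes)) for tid, genes in terms.items()},
        )
        rows = enrich_gene_sets(set(list(bg)[:6]), coll, min_term_size=1)
        return rows, coll

    def test_identical_terms_form_one_group(self):
        rows, coll = self._rows_and_collection(
            {"A": {"G1", "G2", "G3"}, "B": {"G1", "G2", "G3"}}
        )
        groups = group_terms_by_kappa(rows, coll, threshold=0.4)
        assert len(groups) == 1 and set(groups[0].members) == {"A", "B"}

    def test_all_below_threshold_are_singletons(self):
        rows, coll = self._rows_and_collection(
            {"A": {"G1", "G2"}, "B": {"G9", "G10"}, "C": {"G15", "G16"}}
        )
        groups = group_terms_by_kappa(rows, coll, threshold=0.4)
        assert len(groups) == 3

    def test_single_linkage_chains_into_one_group(self):
        terms = {
            "A": {f"G{i}" for i in range(1, 9)},
            "B": {f"G{i}" for i in range(3, 11)},
            "C": {f"G{i}" for i in range(5, 13)},
        }
        rows, coll = self._rows_and_collection(terms)
        bg = coll.background
        k_ab = kappa_score(terms["A"], terms["B"], bg)
        k_bc = kappa_score(terms["B"], terms["C"], bg)
        k_ac = kappa_score(terms["A"], terms["C"], bg)
        assert k_ab >= 0.4 and k_bc >= 0.4 and k_ac < 0.4  # chain premise
        groups = group_terms_by_kappa(rows, coll, threshold=0.4)
        assert len(groups) == 1 and set(groups[0].members) == {"A", "B", "C"}

    def test_group_labeled_by_smallest_p_member(self):
        rows, coll = self._rows_and_collection(
            {"A": {"G1", "G2", "G3"}, "B": {"G1", "G2", "G3", "G15"}}
        )
        groups = group_terms_by_kappa(rows, coll, threshold=0.4)
        best_p = min(rows, key=lambda r: (r.p_value, r.term_id))
        assert groups[0].representative == best_p.term_id


def test_significant_rows_respects_fdr_cut():
    query, coll, planted = simulate_enrichment(seed=5)
    rows = enrich_gene_sets(query, coll)
    sig = significant_rows(rows, fdr=0.05)
    assert all(r.q_value <= 0.05 for r in sig)
    assert planted in {r.term_id for r in sig}
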