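"""Hypergeometric enrichment, Holm adjustment, kappa term clustering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from critnet.enrichment import (
    cluster_terms,
    enrich,
    hypergeom_pvalue,
    kappa_score,
    membership_counts,
    percent_genes_per_term,
)
from critnet.fixtures import colon_grade_terms
from critnet.synthetic import AnnotationTable, generate_annotations


def enumerate_pvalue(k: int, K: int, n: int, U: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(U, n) draws."""
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(U), n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomPvalue:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_pvalue(0, 5, 3, 20) == 1.0

    def test_forced_draw(self):
        assert hypergeom_pvalue(4, 4, 4, 4) == 1.0

    def test_worked_example_against_enumeration(self):
        assert hypergeom_pvalue(2, 3, 3, 10) == pytest.approx(
            enumerate_pvalue(2, 3, 3, 10), abs=1e-12
        )

    def test_matches_enumeration_small_universes(self):
        """Exhaustive-draw oracle over every configuration with U <= 8."""
        for U in range(1, 9):
            for K in range(0, U + 1):
                for n in range(0, U + 1):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_pvalue(k, K, n, U) == pytest.approx(
                            enumerate_pvalue(k, K, n, U), abs=1e-12
                        ), (k, K, n, U)

    def test_non_increasing_in_k(self):
        ps = [hypergeom_pvalue(k, 10, 8, 30) for k in range(9)]
        assert ps == sorted(ps, reverse=True)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 12, 3, 10)


class TestPercentGenesPerTerm:
    @pytest.mark.parametrize(
        "k,K,expected",
        [(3, 100, 3.00), (3, 41, 7.32), (3, 26, 11.54), (3, 27, 11.11),
         (4, 116, 3.45), (5, 5, 100.00)],
    )
    def test_half_up_rounding(self, k, K, expected):
        assert percent_genes_per_term(k, K) == expected

    def test_rounds_half_up_not_bankers(self):
        # 100*1/16 = 6.25 -> 6.25; 100*7/32 = 21.875 -> 21.88 under half-up
        assert percent_genes_per_term(7, 32) == 21.88

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            percent_genes_per_term(0, 10)
        with pytest.raises(ValueError):
            percent_genes_per_term(3, 0)


class TestEnrich:
    def _table(self):
        genes = {f"G{i:03d}" for i in range(1000)}
        terms = (
            ("T0", "query term", frozenset({f"G{i:03d}" for i in range(6)})),
            ("T1", "big term", frozenset({f"G{i:03d}" for i in range(500)})),
            ("T2", "disjoint", frozenset({f"G{i:03d}" for i in range(900, 950)})),
        )
        return AnnotationTable(terms=terms, universe=frozenset(genes))

    def test_exact_query_term_ranks_first(self):
        query = {f"G{i:03d}" for i in range(6)}
        rows = enrich(query, self._table())
        assert rows and rows[0].term_id == "T0"
        assert rows[0].overlap == 6
        assert rows[0].percent_gt == 100.00

    def test_disjoint_term_emits_no_row(self):
        rows = enrich({f"G{i:03d}" for i in range(6)}, self._table(), alpha=1.0 - 1e-12)
        assert "T2" not in {r.term_id for r in rows}

    def test_saturated_query_gives_p_one(self):
        table = self._table()
        for _, _, genes in table.terms:
            p = hypergeom_pvalue(
                len(genes), len(genes), len(table.universe), len(table.universe)
            )
            assert p == 1.0
        # hence nothing can be significant when the query is the whole universe
        assert enrich(set(table.universe), table) == []

    def test_outside_universe_genes_dropped_with_warning(self, caplog):
        query = {f"G{i:03d}" for i in range(6)} | {"NOT_A_GENE"}
        with caplog.at_level("WARNING"):
            rows = enrich(query, self._table())
        assert any("NOT_A_GENE" in r.message for r in caplog.records)
        assert rows[0].overlap == 6

    def test_fully_foreign_query_rejected(self):
        with pytest.raises(ValueError):
            enrich({"X", "Y"}, self._table())

    def test_holm_adjustment_monotone_and_above_raw(self):
        rng = np.random.default_rng(0)
        genes = {f"G{i:03d}" for i in range(300)}
        table = generate_annotations(genes, n_terms=30, min_size=10, max_size=60, seed=1)
        query = set(rng.choice(sorted(genes), size=40, replace=False))
        rows = enrich(query, table, alpha=1.0 - 1e-12)
        assert rows
        for row in rows:
            assert row.adjusted_p >= row.p_value
        ordered = sorted(rows, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in ordered]
        assert adj == sorted(adj)


class TestKappaScore:
    def test_identical_terms(self):
        u = set(range(10))
        assert kappa_score({1, 2, 3}, {1, 2, 3}, u) == pytest.approx(1.0)

    def test_complementary_partition_is_negative(self):
        u = set(range(10))
        a = set(range(5))
        assert kappa_score(a, u - a, u) < 0

    def test_hand_computed_example(self):
        u = {f"g{i}" for i in range(1, 11)}
        assert kappa_score({"g1", "g2"}, {"g2", "g3"}, u) == pytest.approx(0.375)

    def test_constant_equal_vectors_convention(self):
        u = {"a", "b"}
        assert kappa_score(u, u, u) == 1.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.data())
    def test_symmetric_and_relabel_invariant(self, data):
        u = set(range(12))
        a = set(data.draw(st.sets(st.sampled_from(sorted(u)), max_size=12)))
        b = set(data.draw(st.sets(st.sampled_from(sorted(u)), max_size=12)))
        k1 = kappa_score(a, b, u)
        assert k1 == pytest.approx(kappa_score(b, a, u))
        relabel = {i: f"x{i}" for i in u}
        k2 = kappa_score(
            {relabel[i] for i in a}, {relabel[i] for i in b}, set(relabel.values())
        )
        assert k1 == pytest.approx(k2)


class TestClusterTerms:
    def test_single_term_single_cluster(self):
        rows, _ = colon_grade_terms()
        assert cluster_terms(rows[:1]) == {"R01": 1}

    def test_identical_terms_share_cluster(self):
        rows, _ = colon_grade_terms()
        pair = [rows[1], rows[2]]  # identical gene sets
        assignment = cluster_terms(pair, universe={"AKT1", "MAPK3", "SRC", "TP53"})
        assert assignment["R02"] == assignment["R03"]

    def test_curated_table_isolates_hif1(self):
        """Over the six-gene panel the HIF-1 row is the only singleton cluster."""
        rows, query = colon_grade_terms()
        assignment = cluster_terms(rows, threshold=0.4, universe=set(query))
        clusters = {}
        for term, cid in assignment.items():
            clusters.setdefault(cid, set()).add(term)
        assert clusters[assignment["R01"]] == {"R01"}
        assert len(clusters) == 2
        assert len(clusters[assignment["R02"]]) == 33

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            cluster_terms([], threshold=0.0)


class TestMembershipCounts:
    def test_empty_rows_all_zero(self):
        assert membership_counts([], ["AKT1", "TP53"]) == {"AKT1": 0, "TP53": 0}

    def test_counts_use_normalized_gene_sets(self):
        rows, query = colon_grade_terms()
        counts = membership_counts(rows, sorted(query))
        # row 1 prints the APK3 variant; normalization credits it to MAPK3
        assert counts["MAPK3"] == 34
        assert counts["GAPDH"] == 1


def test_null_enrichment_calibration():
    """Empirical p < 0.05 rate matches the discrete test's exact size.

    The right-tailed hypergeometric test is discrete, so its exact size at
    alpha = 0.05 sits below 0.05; the simulated rate must agree with that
    size (computed independently from the null pmf) within 3 SE and must
    never exceed the nominal rate by more than 3 SE.
    """
    from scipy import stats as sps

    genes = {f"G{i:04d}" for i in range(1000)}
    table = generate_annotations(genes, n_terms=40, min_size=50, max_size=200, seed=7)
    pool = sorted(table.universe)
    U, n = len(pool), 100
    sizes = np.array([len(g) for _, _, g in table.terms])
    member = np.zeros((len(sizes), U), dtype=bool)
    index = {g: i for i, g in enumerate(pool)}
    for ti, (_, _, term_genes) in enumerate(table.terms):
        for g in term_genes:
            member[ti, index[g]] = True
    rng = np.random.default_rng(7)
    fractions = []
    for _ in range(500):
        draw = rng.choice(U, size=n, replace=False)
        ks = member[:, draw].sum(axis=1)
        pvals = np.array(
            [hypergeom_pvalue(int(k), int(K), n, U) for k, K in zip(ks, sizes)]
        )
        fractions.append((pvals < 0.05).mean())
    fractions = np.asarray(fractions)
    exact_size = np.mean(
        [
            sps.hypergeom.pmf(np.arange(0, min(K, n) + 1), U, K, n)[
                sps.hypergeom.sf(np.arange(0, min(K, n) + 1) - 1, U, K, n) < 0.05
            ].sum()
            for K in sizes
        ]
    )
    se = fractions.std(ddof=1) / math.sqrt(len(fractions))
    assert abs(fractions.mean() - exact_size) < 3 * se
    assert fractions.mean() < 0.05 + 3 * se
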