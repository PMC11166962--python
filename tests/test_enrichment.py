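from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from crosstrait import DomainError, FormatError
from crosstrait.enrichment import (
    EnrichmentAnalysis,
    GeneSetTerm,
    cluster_terms,
    enrich,
    hypergeometric_p,
    read_gmt,
    shared_clusters,
    term_similarity,
    write_gmt,
)


def _term(term_id, members, name=None):
    return GeneSetTerm(term_id=term_id, name=name or term_id, source="custom",
                       members=frozenset(members))


def exact_upper_tail(k, n, K, N):
    """Independent oracle: exact rational pmf summation."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


class TestGmtIO:
    def test_two_line_file(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("T1\tfirst\tg1\tg2\tg3\nT2\tsecond\tg2\tg4\n")
        terms = read_gmt(path)
        assert [t.term_id for t in terms] == ["T1", "T2"]
        assert terms[0].members == {"g1", "g2", "g3"}

    def test_repeated_gene_deduplicated(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("T1\tx\tg1\tg1\tg2\n")
        assert read_gmt(path)[0].members == {"g1", "g2"}

    def test_short_line_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("T1\tonly-description\n")
        with pytest.raises(FormatError, match="line 1"):
            read_gmt(path)

    def test_round_trip_preserves_membership(self, tmp_path):
        terms = [_term("A", {"g1", "g2"}), _term("B", {"g3", "g2", "g9"})]
        path = tmp_path / "t.gmt"
        write_gmt(terms, path)
        back = read_gmt(path)
        assert {(t.term_id, t.members) for t in back} == {
            (t.term_id, t.members) for t in terms
        }


class TestHypergeometricP:
    def test_worked_example(self):
        # C(5,3)C(15,2) + C(5,4)C(15,1) + C(5,5) over C(20,5) = 1126/15504
        assert hypergeometric_p(3, 5, 5, 20) == pytest.approx(1126 / 15504, rel=1e-12)

    def test_zero_overlap_gives_one(self):
        assert hypergeometric_p(0, 5, 5, 20) == 1.0

    def test_degenerate_certain_overlap(self):
        assert hypergeometric_p(4, 4, 4, 4) == pytest.approx(1.0)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(DomainError):
            hypergeometric_p(6, 5, 5, 20)
        with pytest.raises(DomainError):
            hypergeometric_p(1, 5, 25, 20)


class TestEnrich:
    def test_factor_and_significance_thresholds(self):
        terms = [_term("T1", {f"g{i}" for i in range(5)})]
        query = {f"g{i}" for i in range(3)} | {"h1", "h2"}
        background = {f"g{i}" for i in range(5)} | {f"h{i}" for i in range(15)}
        (res,) = enrich(query, terms, background)
        assert res.k == 3 and res.n == 5 and res.K == 5 and res.N == 20
        assert res.enrichment_factor == pytest.approx(2.4)
        # p ~ 0.0726 is above the 0.01 cut: not significant despite k and factor
        assert res.p == pytest.approx(1126 / 15504, rel=1e-9)
        assert not res.significant

    def test_disjoint_term_not_significant(self):
        terms = [_term("T1", {"x1", "x2", "x3"})]
        results = enrich({"q1", "q2"}, terms, {"x1", "x2", "x3", "q1", "q2", "z"})
        assert results[0].k == 0 and results[0].p == 1.0 and not results[0].significant

    def test_empty_query_rejected(self):
        with pytest.raises(DomainError):
            enrich(set(), [_term("T", {"a"})], {"a"})

    def test_query_outside_background_intersected(self):
        terms = [_term("T1", {"a", "b", "c"})]
        results = enrich({"a", "zzz"}, terms, {"a", "b", "c", "d"})
        assert results[0].n == 1


class TestKappaSimilarity:
    def test_worked_example(self):
        ref = [f"g{i}" for i in range(1, 7)]
        kappa = term_similarity(frozenset({"g1", "g2", "g3"}),
                                frozenset({"g1", "g2", "g4"}), ref)
        assert kappa == pytest.approx(1 / 3)

    def test_identical_memberships_give_one(self):
        ref = ["a", "b", "c", "d"]
        assert term_similarity(frozenset("ab"), frozenset("ab"), ref) == 1.0

    def test_complementary_memberships_negative(self):
        ref = ["a", "b", "c", "d"]
        assert term_similarity(frozenset("ab"), frozenset("cd"), ref) < 0

    def test_degenerate_marginals(self):
        ref = ["a", "b"]
        assert term_similarity(frozenset("ab"), frozenset("ab"), ref) == 1.0
        assert term_similarity(frozenset(), frozenset("ab"), ref) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 15), min_size=1, max_size=10),
        b=st.sets(st.integers(0, 15), min_size=1, max_size=10),
    )
    def test_symmetry(self, a, b):
        ref = list(range(16))
        assert term_similarity(frozenset(a), frozenset(b), ref) == pytest.approx(
            term_similarity(frozenset(b), frozenset(a), ref)
        )

    def test_outside_reference_genes_act_only_through_chance_agreement(self):
        """Adding reference genes in neither term changes kappa only via p_e."""
        a, b = frozenset({"g1", "g2"}), frozenset({"g1", "g3"})
        small_ref = ["g1", "g2", "g3", "g4"]
        big_ref = small_ref + ["x1", "x2", "x3", "x4"]
        # by hand from the kappa formula at each reference size
        def kappa_by_hand(ref):
            n = len(ref)
            both, only_a, only_b = 1, 1, 1
            neither = n - 3
            p_o = (both + neither) / n
            pa = pb = 2 / n
            p_e = pa * pb + (1 - pa) * (1 - pb)
            return (p_o - p_e) / (1 - p_e)

        assert term_similarity(a, b, small_ref) == pytest.approx(kappa_by_hand(small_ref))
        assert term_similarity(a, b, big_ref) == pytest.approx(kappa_by_hand(big_ref))
        assert term_similarity(a, b, small_ref) != pytest.approx(
            term_similarity(a, b, big_ref)
        )


def _result(term, p, label="Q", significant=True, k=5, overlap=frozenset()):
    from crosstrait.enrichment import EnrichmentResult

    return EnrichmentResult(
        term=term, query_label=label, k=k, n=10, K=len(term.members), N=100,
        p=p, q=p, enrichment_factor=3.0, significant=significant,
        overlap_genes=overlap,
    )


class TestClusterTerms:
    def test_single_linkage_transitive_closure(self):
        # A-B and B-C similar (kappa 0.64), A-C below threshold (kappa 0.28):
        # one cluster by transitivity, plus the unrelated D as a singleton
        a = _term("A", {"g1", "g2", "g3", "g4"})
        b = _term("B", {"g1", "g2", "g3", "g5"})
        c = _term("C", {"g2", "g3", "g5", "g6"})
        d = _term("D", {f"x{i}" for i in range(6)})
        results = [_result(a, 1e-5), _result(b, 1e-3), _result(c, 1e-2), _result(d, 1e-4)]
        clusters = cluster_terms(results, threshold=0.3)
        by_members = {frozenset(cl.member_ids) for cl in clusters}
        assert by_members == {frozenset({"A", "B", "C"}), frozenset({"D"})}

    def test_low_similarity_gives_singletons(self):
        terms = [_term(f"T{i}", {f"x{i}a", f"x{i}b", f"x{i}c"}) for i in range(4)]
        clusters = cluster_terms([_result(t, 1e-3) for t in terms], threshold=0.3)
        assert len(clusters) == 4

    def test_named_by_most_significant_member(self):
        a = _term("A", {"g1", "g2", "g3"}, name="weak pathway")
        b = _term("B", {"g1", "g2", "g4"}, name="strong pathway")
        clusters = cluster_terms([_result(a, 1e-3), _result(b, 1e-5)], threshold=0.1)
        assert clusters[0].name == "strong pathway"
        assert clusters[0].representative.term_id == "B"

    def test_raising_threshold_never_merges_more(self):
        rng_terms = [
            _term(f"T{i}", {f"g{j}" for j in range(i, i + 4)}) for i in range(6)
        ]
        results = [_result(t, 1e-3) for t in rng_terms]
        counts = [
            len(cluster_terms(results, threshold=t)) for t in (0.1, 0.3, 0.5, 0.8)
        ]
        assert counts == sorted(counts)

    def test_clusters_partition_significant_terms(self):
        terms = [_term(f"T{i}", {f"g{j}" for j in range(i, i + 5)}) for i in range(5)]
        results = [_result(t, 1e-3) for t in terms]
        clusters = cluster_terms(results, threshold=0.3)
        all_ids = [tid for c in clusters for tid in c.member_ids]
        assert sorted(all_ids) == sorted(t.term_id for t in terms)


class TestSharedClusters:
    def test_flags_and_per_query_gene_counts(self):
        term = _term("T1", {f"g{i}" for i in range(200)})
        genes_a = frozenset(f"g{i}" for i in range(35))            # 35 query-A genes
        genes_b = frozenset(f"g{i}" for i in range(11, 164))       # 153 query-B genes
        results = {
            "A": [_result(term, 1e-4, label="A", overlap=genes_a)],
            "B": [_result(term, 1e-6, label="B", overlap=genes_b)],
        }
        clusters = cluster_terms(results["A"] + results["B"], threshold=0.3)
        flagged = shared_clusters(clusters, results)
        (c,) = flagged
        assert c.shared
        assert c.gene_counts == {"A": 35, "B": 153}
        assert c.overlap_count == 24

    def test_single_query_significance_is_not_shared(self):
        term = _term("T1", {"g1", "g2", "g3"})
        results = {
            "A": [_result(term, 1e-4, label="A")],
            "B": [_result(term, 0.5, label="B", significant=False)],
        }
        flagged = shared_clusters(cluster_terms(results["A"], threshold=0.3), results)
        assert not flagged[0].shared


class TestEnrichmentAnalysis:
    def test_planted_terms_end_in_shared_clusters(self, small_dataset):
        res = EnrichmentAnalysis(
            small_dataset.expanded_sets, small_dataset.terms
        ).fit()
        shared_ids = {
            tid for c in res.clusters if c.shared for tid in c.member_ids
        }
        for tid in small_dataset.enriched_term_ids:
            assert tid in shared_ids
        frame = res.cluster_frame()
        assert bool(frame["shared"].any())
        assert "Clusters" in res.summary()
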