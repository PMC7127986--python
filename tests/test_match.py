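"""Match classification, disease lineage distance and search semantics."""

import pytest

from metakb.diseases import disease_distance
from metakb.match import (DiseaseMode, QueryVariant, SearchStrategy,
                          StrategyError, classify_variant_match, match_patient,
                          match_gene_level, search)
from metakb.adapters import CohortSample, CohortVariant
from metakb.model import GenomicInterval, MatchClass, Tier
from metakb.resources import load_coordinate_lookup, load_ontology

GRAPH = load_ontology()


def iv(start, end, alt="", chrom="1"):
    return GenomicInterval("GRCh37", chrom, start, end, "", alt)


def brute_force_classify(q, t, q_alt, t_alt):
    """Independent classifier by direct set intersection of base positions."""
    qset, tset = set(range(*q)), set(range(*t))
    inter = len(qset & tset)
    if inter == 0:
        return MatchClass.NONE
    complete = qset == tset
    if complete:
        return MatchClass.EXACT if (q_alt and q_alt == t_alt) \
            else MatchClass.POSITIONAL
    if inter / len(qset) > 0.10 and inter / len(tset) > 0.10:
        return MatchClass.FOCAL
    return MatchClass.REGIONAL


class TestClassification:
    def test_exact_requires_matching_alt(self):
        assert classify_variant_match(iv(100, 110, "T"), iv(100, 110, "T")) \
            is MatchClass.EXACT

    def test_same_locus_different_alt_is_positional(self):
        assert classify_variant_match(iv(100, 110, "G"), iv(100, 110, "T")) \
            is MatchClass.POSITIONAL

    def test_half_overlap_is_focal(self):
        assert classify_variant_match(iv(100, 200), iv(150, 250)) \
            is MatchClass.FOCAL

    def test_reciprocity_failure_is_regional(self):
        # target fully inside query but only ~1% of the query overlaps
        assert classify_variant_match(iv(100, 1000), iv(150, 160)) \
            is MatchClass.REGIONAL

    def test_disjoint_is_none(self):
        assert classify_variant_match(iv(0, 10), iv(20, 30)) is MatchClass.NONE

    def test_different_chromosome_is_none(self):
        assert classify_variant_match(iv(0, 10, chrom="1"),
                                      iv(0, 10, chrom="2")) is MatchClass.NONE

    def test_zero_length_query_raises(self):
        with pytest.raises(ValueError):
            classify_variant_match(iv(5, 5), iv(0, 10))

    def test_exhaustive_small_intervals_match_brute_force(self):
        """All integer interval pairs within [0, 20) agree with the
        brute-force classifier, including the reciprocal-0.10 boundary."""
        pairs = [(s, e) for s in range(20) for e in range(s + 1, 21)]
        for q in pairs:
            for t in pairs:
                for q_alt, t_alt in (("T", "T"), ("G", "T")):
                    got = classify_variant_match(iv(*q, q_alt), iv(*t, t_alt))
                    want = brute_force_classify(q, t, q_alt, t_alt)
                    assert got is want, (q, t, q_alt, t_alt, got, want)


class TestDiseaseDistance:
    def test_parent_child_within_topnode_scores_zero(self):
        assert disease_distance("DOID:3008", "DOID:3007", GRAPH) == 0

    def test_siblings_never_match_even_sharing_a_topnode(self):
        assert disease_distance("DOID:0050938", "DOID:3007", GRAPH) is None

    def test_identity_scores_zero(self):
        assert disease_distance("DOID:3910", "DOID:3910", GRAPH) == 0

    def test_crossing_a_topnode_boundary_counts_it(self):
        # lung adenocarcinoma up to the cancer root crosses lung cancer
        assert disease_distance("DOID:3910", "DOID:162", GRAPH) == 1
        assert disease_distance("DOID:3910", "DOID:1324", GRAPH) == 0

    def test_verdict_is_symmetric(self):
        nodes = list(GRAPH.graph.nodes)
        for a in nodes:
            for b in nodes:
                assert (disease_distance(a, b, GRAPH) is None) == \
                       (disease_distance(b, a, GRAPH) is None)

    def test_all_pairs_inside_one_topnode_subtree_score_zero(self):
        subtree = [d for d in GRAPH.graph.nodes
                   if "DOID:1612" in GRAPH.ancestors_or_self(d)]
        for a in subtree:
            for b in subtree:
                dist = disease_distance(a, b, GRAPH)
                assert dist in (None, 0)


ERBB2_DUP = load_coordinate_lookup()[("ERBB2", "y772_a775dup")]


class TestSearch:
    def test_exact_query_hits_only_allele_specific_sources(self, table2_store):
        results = search(QueryVariant(ERBB2_DUP, gene="ERBB2"), None,
                         table2_store, SearchStrategy(MatchClass.EXACT))
        sources = {r.association.source.value for r in results}
        assert sources == {"CIViC", "CGI", "JAX-CKB", "MMatch"}
        assert all(r.match_class is MatchClass.EXACT for r in results)

    def test_relaxing_variant_mode_grows_the_result_set(self, table2_store):
        query = QueryVariant(ERBB2_DUP, gene="ERBB2")
        prev: set = set()
        for mode in (MatchClass.EXACT, MatchClass.POSITIONAL, MatchClass.FOCAL,
                     MatchClass.REGIONAL, MatchClass.GENE_LEVEL):
            hits = {(r.association.source.value, r.association.record_id)
                    for r in search(query, None, table2_store,
                                    SearchStrategy(mode))}
            assert hits >= prev
            prev = hits
        assert len(prev) == len(table2_store)  # gene level reaches everything

    def test_results_sorted_by_evidence_then_specificity(self, table2_store):
        results = search(QueryVariant(ERBB2_DUP, gene="ERBB2"), None,
                         table2_store, SearchStrategy(MatchClass.GENE_LEVEL))
        ranks = [(r.level.rank, r.match_class.rank) for r in results]
        assert ranks == sorted(ranks)

    def test_tier_filter_with_non_exact_mode_is_refused(self, table2_store):
        strategy = SearchStrategy(MatchClass.REGIONAL, DiseaseMode.ANY, Tier.I)
        with pytest.raises(StrategyError):
            search(QueryVariant(ERBB2_DUP), None, table2_store, strategy)

    def test_grouped_disease_mode_restricts_to_lineage(self, table2_store):
        query = QueryVariant(ERBB2_DUP, gene="ERBB2")
        grouped = search(query, "DOID:3910", table2_store,
                         SearchStrategy(MatchClass.EXACT, DiseaseMode.GROUPED),
                         GRAPH)
        anymode = search(query, "DOID:3910", table2_store,
                         SearchStrategy(MatchClass.EXACT, DiseaseMode.ANY))
        assert grouped and len(grouped) <= len(anymode)
        assert all(r.disease_distance == 0 for r in grouped)
        # every grouped hit's disease shares lineage within the lung subtree
        for r in grouped:
            assert r.association.disease.topnode == "DOID:1324"


class TestPatientMatching:
    def _sample(self, doid="DOID:3910"):
        return CohortSample("S1", "P1", "LUAD", doid)

    def _variant(self):
        return CohortVariant("S1", "ERBB2", ERBB2_DUP, "In_Frame_Ins")

    def test_exact_tier1_hit_yields_tier1_best_level(self, table2_store):
        summary = match_patient(
            [self._variant()], self._sample(), table2_store,
            SearchStrategy(MatchClass.EXACT, DiseaseMode.ANY, Tier.I), GRAPH)
        assert summary.best_level is not None
        assert summary.best_level.rank <= 1  # A or B

    def test_sample_without_variants_keeps_zero_matches(self, table2_store):
        summary = match_patient([], self._sample(), table2_store,
                                SearchStrategy(MatchClass.REGIONAL), GRAPH)
        assert summary.n_matches == 0 and summary.best_level is None

    def test_best_level_is_minimum_rank_over_matches(self, table2_store):
        summary = match_patient([self._variant()], self._sample(), table2_store,
                                SearchStrategy(MatchClass.EXACT), GRAPH)
        levels = sorted(r.evidence.harmonized_level.rank for r in table2_store
                        if any(v.allele_key for v in r.variants))
        assert summary.best_level.rank == levels[0]

    def test_gene_level_matching_by_symbol_only(self, table2_store):
        hits = match_gene_level([self._variant()], table2_store)
        assert len(hits) == len(table2_store)
        none = match_gene_level(
            [CohortVariant("S1", "GENE9", iv(5, 6, "T"), "Missense_Mutation")],
            table2_store)
        assert none == []
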