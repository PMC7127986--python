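"""Consensus statistics: overlap, UpSet attribution, Fisher tests, ratios."""

import math
from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from metakb.stats import (ContingencyTable2x2, ElementSets, element_sets,
                          fisher_or, interpretations_per_publication,
                          membership_from_sets, normalize_document,
                          overlap_fraction, upset_attribution,
                          disease_group_proportions)


def fisher_p_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(k):
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_symmetric_table(self):
        oddsratio, p = fisher_or(ContingencyTable2x2(1, 1, 1, 1))
        assert oddsratio == 1.0 and p == 1.0

    def test_zero_cell_reports_infinite_or(self):
        oddsratio, p = fisher_or(ContingencyTable2x2(5, 0, 2, 7))
        assert math.isinf(oddsratio) and 0 < p <= 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(1, -1, 0, 2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_p_agrees_with_enumeration_oracle_on_small_tables(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return  # degenerate margin: p = 1 by convention, skip comparison
        _, p = fisher_or(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_p_oracle(a, b, c, d), rel=1e-9)

    def test_or_is_the_sample_cross_ratio(self):
        oddsratio, _ = fisher_or(ContingencyTable2x2(3, 4, 5, 6))
        assert oddsratio == pytest.approx(3 * 6 / (4 * 5))


class TestOverlap:
    def test_hand_enumerated_example(self):
        sets = ElementSets("gene", {"A": {"x", "y"}, "B": {"y", "z"}})
        result = overlap_fraction(sets)
        assert result.union_size == 3
        assert result.multiplicity == {1: 2, 2: 1}
        assert result.overlap_percent == pytest.approx(100 / 3)

    def test_identical_sets_overlap_fully(self):
        sets = ElementSets("gene", {s: {"a", "b"} for s in "ABCDEF"})
        assert overlap_fraction(sets).overlap_percent == 100.0

    def test_disjoint_sets_do_not_overlap(self):
        sets = ElementSets("gene", {"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert overlap_fraction(sets).overlap_percent == 0.0

    def test_multiplicity_histogram_sums_to_union(self, store):
        for kind in ("gene", "variant", "disease", "drug", "publication"):
            result = overlap_fraction(element_sets(store, kind))
            assert sum(result.multiplicity.values()) == result.union_size

    def test_single_source_is_an_error(self):
        with pytest.raises(ValueError):
            overlap_fraction(ElementSets("gene", {"A": {"x"}}))


class TestUpset:
    def test_element_in_all_sources_attributed_to_full_combination(self):
        membership = {"v": {"A", "B", "C", "D", "E", "F"}, "w": {"B"}}
        attribution = upset_attribution(membership)
        assert attribution["v"] == ("A", "B", "C", "D", "E", "F")
        assert attribution["w"] == ("B",)

    def test_attribution_partitions_the_element_universe(self, store):
        sets = element_sets(store, "variant")
        membership = membership_from_sets(sets)
        attribution = upset_attribution(membership)
        from collections import Counter
        combo_counts = Counter(attribution.values())
        assert sum(combo_counts.values()) == len(membership)


class TestDocumentNormalization:
    @pytest.mark.parametrize("spelling", ["PMID: 123", "pmid:123", "123",
                                          "PMID:123"])
    def test_pmid_spellings_coalesce(self, spelling):
        assert normalize_document(spelling) == "PMID:123"

    def test_doi_lowercased_and_prefix_stripped(self):
        assert normalize_document("doi:10.1000/ABC") == "10.1000/abc"


class TestPublications:
    def test_simple_ratio(self):
        from metakb.model import (Association, DiseaseNorm, Evidence,
                                  EvidenceLevel, GeneNorm, GeneStatus,
                                  RawInterpretation, Source, Tier,
                                  VariantNorm)

        def assoc(i, docs):
            return Association(
                Source.CIVIC, f"r{i}",
                GeneNorm("BRAF", "primary", GeneStatus.NORMALIZED),
                (VariantNorm("V600E"),), DiseaseNorm(), None,
                Evidence("Level C", EvidenceLevel.C, Tier.II,
                         documents=tuple(docs)),
                RawInterpretation(Source.CIVIC, f"r{i}", {}))

        summary = interpretations_per_publication(
            [assoc(0, ["PMID:1"]), assoc(1, ["PMID:1"]), assoc(2, ["PMID:2"])])
        assert summary.ratio == pytest.approx(1.5)
        assert summary.n_unique_documents == 2

    def test_erbb2_worked_example_document_accounting(self, table2_store):
        """The ERBB2 exon-20 fixture cites 22 distinct documents; one PMID
        (26598547) is cited by three sources, every other shared document by
        exactly two."""
        summary = interpretations_per_publication(table2_store)
        assert summary.n_interpretations == 30
        assert summary.n_unique_documents == 22
        assert summary.shared_documents["PMID:26598547"] == 3
        others = {d: n for d, n in summary.shared_documents.items()
                  if d != "PMID:26598547"}
        assert others and set(others.values()) == {2}


class TestDiseaseGroups:
    def test_fractions_sum_to_one_and_threshold_flags(self, store):
        groups = disease_group_proportions(store)
        assert sum(f for f, _ in groups.values()) == pytest.approx(1.0)
        for fraction, flagged in groups.values():
            assert flagged == (fraction >= 0.05)

    def test_empty_store_is_an_error(self):
        with pytest.raises(ValueError):
            disease_group_proportions([])
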