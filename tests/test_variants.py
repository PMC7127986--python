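"""Coordinate inference, genomic HGVS, allele keys and protein edits."""

import pytest
from hypothesis import given, settings, strategies as st

from metakb.genes import normalize_gene
from metakb.model import GenomicInterval, VariantCategory
from metakb.resources import (ERBB2_KINASE_WINDOW, load_accessions,
                              load_coordinate_lookup, load_gene_loci,
                              load_gene_table)
from metakb.variants import (AccessionLookupError, HgvsSyntaxError,
                             ProteinContext, ReferenceMismatchError,
                             ReferenceSlice, assemble_hgvs_g,
                             canonical_allele_key, infer_coordinates,
                             normalize_protein_change, parse_hgvs_g)

ACC = load_accessions()
LOOKUP = load_coordinate_lookup()
LOCI = load_gene_loci()
GENES = load_gene_table()


class TestCoordinateInference:
    def test_lookup_hit_returns_table_interval(self):
        gene = normalize_gene("BRAF", GENES)
        inf = infer_coordinates("V600E", gene, LOOKUP, LOCI)
        assert inf.interval == LOOKUP[("BRAF", "v600e")]
        assert inf.category is VariantCategory.ALLELE_SPECIFIC

    def test_decorated_labels_resolve(self):
        gene = normalize_gene("BRAF", GENES)
        for label in ("BRAF:V600E", "BRAF V600E", "p.V600E"):
            assert infer_coordinates(label, gene, LOOKUP, LOCI).interval \
                == LOOKUP[("BRAF", "v600e")]

    def test_amplification_maps_to_full_gene_locus(self):
        gene = normalize_gene("GENE1", GENES)
        inf = infer_coordinates("amplification", gene, LOOKUP, LOCI)
        assert inf.category is VariantCategory.CATEGORICAL
        assert (inf.interval.chromosome, inf.interval.start,
                inf.interval.end) == ("1", 1000, 5000)

    @pytest.mark.parametrize("label", ["oncogenic mutations",
                                       "loss-of-function mutation",
                                       "overexpression"])
    def test_other_categorical_labels_use_gene_locus(self, label):
        gene = normalize_gene("KRAS", GENES)
        inf = infer_coordinates(label, gene, LOOKUP, LOCI)
        assert inf.category is VariantCategory.CATEGORICAL
        assert inf.interval == LOCI["KRAS"]

    def test_unknown_label_is_unresolved(self):
        gene = normalize_gene("GENE1", GENES)
        inf = infer_coordinates("made-up-label-xyz", gene, LOOKUP, LOCI)
        assert inf.interval is None
        assert inf.category is VariantCategory.UNRESOLVED

    def test_explicit_coordinates_pass_through(self):
        iv = GenomicInterval("GRCh37", "7", 5, 6, "A", "G")
        gene = normalize_gene("BRAF", GENES)
        inf = infer_coordinates("whatever", gene, LOOKUP, LOCI, explicit=iv)
        assert inf.interval is iv


class TestHgvsAssembly:
    def test_substitution(self):
        iv = GenomicInterval("GRCh37", "7", 140453135, 140453136, "A", "T")
        assert assemble_hgvs_g(iv, ACC) == "NC_000007.13:g.140453136A>T"

    def test_deletion_form_parses_under_grammar(self):
        iv = GenomicInterval("GRCh37", "12", 99, 102, "ACG", "")
        hgvs = assemble_hgvs_g(iv, ACC)
        assert hgvs == "NC_000012.11:g.100_102del"
        parsed = parse_hgvs_g(hgvs)
        assert (parsed.start, parsed.end, parsed.kind) == (99, 102, "del")

    def test_insertion_form(self):
        iv = GenomicInterval("GRCh37", "1", 105, 105, "", "TTA")
        assert assemble_hgvs_g(iv, ACC) == "NC_000001.10:g.105_106insTTA"

    def test_unknown_chromosome_raises_naming_key(self):
        iv = GenomicInterval("GRCh37", "chrUn", 5, 6, "A", "T")
        with pytest.raises(AccessionLookupError) as err:
            assemble_hgvs_g(iv, ACC)
        assert "chrUn" in str(err.value)

    @pytest.mark.parametrize("bad", [
        "g.100A>T", "NC_000001.10:g.100A>U", "NC_000001.10:g.100_99del",
        "NC_000001.10:g.100_102insA", "NC_000001.10:c.100A>T"])
    def test_grammar_rejects_malformed_strings(self, bad):
        with pytest.raises(HgvsSyntaxError):
            parse_hgvs_g(bad)


def _apply(slice_, hgvs):
    """Brute-force oracle: apply a parsed edit to the slice sequence."""
    p = parse_hgvs_g(hgvs)
    s, e = p.start - slice_.offset, p.end - slice_.offset
    ref = slice_.sequence[s:e]
    alt = ref + ref if p.kind == "dup" else (p.alt or "")
    return slice_.sequence[:s] + alt + slice_.sequence[e:]


class TestAlleleKeys:
    def test_same_substitution_twice_gives_equal_keys(self):
        sl = ReferenceSlice("GRCh37", "1", 90, "GATTACAGATTACAGATTACA")
        h = "NC_000001.10:g.95A>C"
        assert canonical_allele_key(h, sl) == canonical_allele_key(h, sl)

    def test_equivalent_insertions_in_homopolymer_run(self):
        # reference run AAAA at 1-based 103-106; inserting A anywhere in the
        # run yields the same sequence, hence the same key
        sl = ReferenceSlice("GRCh37", "1", 100, "GCAAAATCGGT")
        left = "NC_000001.10:g.103_104insA"
        right = "NC_000001.10:g.105_106insA"
        assert _apply(sl, left) == _apply(sl, right)
        assert canonical_allele_key(left, sl) == canonical_allele_key(right, sl)

    def test_substitution_with_wrong_ref_raises(self):
        sl = ReferenceSlice("GRCh37", "1", 100, "GCAAAATCGGT")
        with pytest.raises(ReferenceMismatchError):
            canonical_allele_key("NC_000001.10:g.101C>T", sl)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        unit=st.text(alphabet="ACGT", min_size=1, max_size=3),
        repeats=st.integers(2, 5),
        flank=st.text(alphabet="ACGT", min_size=3, max_size=8),
        offset_a=st.integers(0, 5),
        offset_b=st.integers(0, 5),
    )
    def test_keys_invariant_under_shifts_within_repeat_runs(
            self, unit, repeats, flank, offset_a, offset_b):
        """Two spellings of the same insertion inside a repeat run get one
        key, verified against a sequence-application oracle."""
        offset_a = min(offset_a, repeats) * len(unit)
        offset_b = min(offset_b, repeats) * len(unit)
        seq = flank + unit * repeats + flank
        sl = ReferenceSlice("GRCh37", "1", 1000, seq)
        run_start = 1000 + len(flank)  # 0-based start of the repeat run

        def ins_at(off):  # insertion of one unit at a unit boundary
            pos = run_start + off  # 0-based insertion point
            return f"NC_000001.10:g.{pos}_{pos + 1}ins{unit}"

        a, b = ins_at(offset_a), ins_at(offset_b)
        assert _apply(sl, a) == _apply(sl, b)
        assert canonical_allele_key(a, sl) == canonical_allele_key(b, sl)


class TestProteinNormalization:
    @pytest.mark.parametrize("edit", ["E770delinsEAYVM", "M774insAYVM",
                                      "A775_G776insYVMA", "Y772_A775dup"])
    def test_all_spellings_of_the_exon20_duplication_collapse(self, edit):
        assert normalize_protein_change(ERBB2_KINASE_WINDOW, edit) \
            == "Y772_A775dup"

    def test_non_duplicating_insertion_stays_insertion(self):
        assert normalize_protein_change(ERBB2_KINASE_WINDOW,
                                        "A775_G776insQQ") == "A775_G776insQQ"

    def test_insertion_shifts_to_three_prime_most_position(self):
        # inserting A before or within the AA run lands at the run's 3' end
        ctx = ProteinContext("MKAAQG", 100)
        assert normalize_protein_change(ctx, "K101insA") == "A103dup"

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            normalize_protein_change(ERBB2_KINASE_WINDOW, "K770delinsEA")

    def test_substitution_and_deletion_forms(self):
        ctx = ProteinContext("EAYVMAG", 770)
        assert normalize_protein_change(ctx, "Y772F") == "Y772F"
        assert normalize_protein_change(ctx, "Y772_V773del") == "Y772_V773del"

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        window=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5,
                       max_size=12),
        start=st.integers(1, 900),
        pos=st.integers(1, 10),
        ins=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=4),
    )
    def test_normalization_is_idempotent(self, window, start, pos, ins):
        """normalize(normalize(e)) == normalize(e), and both describe the
        same mutated sequence as the original edit (brute-force check)."""
        from metakb.variants import _apply_protein_edit
        ctx = ProteinContext(window, start)
        pos = min(pos, len(window) - 2)
        anchor = window[pos]
        edit = f"{anchor}{start + pos}ins{ins}"
        try:
            canonical = normalize_protein_change(ctx, edit)
        except Exception:
            return  # boundary insertions may be inexpressible in this window
        assert normalize_protein_change(ctx, canonical) == canonical
        assert _apply_protein_edit(ctx, canonical) == _apply_protein_edit(ctx, edit)
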