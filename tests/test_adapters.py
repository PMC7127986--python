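"""Dialect readers/writers, MAF conventions and consequence filtering."""

import json

import pytest

from metakb.adapters import (EXCLUDED_CONSEQUENCES, FormatError,
                             filter_by_consequence, read_clinical, read_maf,
                             read_source_dump, write_maf, write_source_dump)
from metakb.model import Source
from metakb.resources import load_oncotree_map
from metakb.synthetic import _DUMP_FILENAMES


@pytest.mark.parametrize("source", list(Source))
def test_dialect_round_trip(kb_paths, tmp_path, source):
    """read(write(records)) reproduces every record payload verbatim."""
    records = read_source_dump(kb_paths[source], source).records
    assert records, source
    out = tmp_path / _DUMP_FILENAMES[source]
    write_source_dump(records, out, source)
    again = read_source_dump(out, source).records
    assert [r.payload for r in again] == [r.payload for r in records]
    assert [r.record_id for r in again] == [r.record_id for r in records]


def test_cgi_tsv_row_count_preserved(tmp_path):
    path = tmp_path / "cgi.tsv"
    path.write_text(
        "Record_ID\tGene\tAlteration\tPrimary_Tumor_Type\tDrug\t"
        "Evidence_Level\tAssociation\tSource\n"
        "cgi-1\tBRAF\tV600E\tmelanoma\tvemurafenib\tClinical practice\t"
        "Responsive\tPMID: 1\n"
        "cgi-2\tKRAS\tG12D\tcolorectal cancer\t\tPreclinical data\t"
        "Responsive\tPMID: 2\n"
        "cgi-3\tEGFR\tL858R\tlung cancer\tgefitinib\tEarly trials\t"
        "Responsive\tPMID: 3\n")
    result = read_source_dump(path, Source.CGI)
    assert len(result.records) == 3
    assert all(r.source is Source.CGI for r in result.records)
    assert not result.rejects


def test_record_missing_identifier_goes_to_rejects(kb_paths, tmp_path):
    payloads = [r.payload for r in
                read_source_dump(kb_paths[Source.CIVIC], Source.CIVIC).records]
    broken = [dict(p) for p in payloads]
    del broken[1]["id"]
    path = tmp_path / "broken.json"
    path.write_text(json.dumps(broken))
    result = read_source_dump(path, Source.CIVIC)
    assert len(result.records) == len(payloads) - 1
    assert len(result.rejects) == 1
    assert "identifier" in result.rejects[0].reason


def test_json_dialect_shape_mismatch_raises_format_error(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"not": "a list"}')
    with pytest.raises(FormatError):
        read_source_dump(path, Source.ONCOKB)


_MAF_HEADER = ("Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\t"
               "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
               "Tumor_Sample_Barcode\n")


def test_maf_snv_coordinate_conversion(tmp_path):
    """1-based inclusive SNV at 100 becomes the half-open interval [99, 100)."""
    path = tmp_path / "one.maf"
    path.write_text(_MAF_HEADER +
                    "BRAF\t7\t100\t100\tA\tT\tMissense_Mutation\tS1\n")
    (v,) = read_maf(path)
    assert (v.interval.start, v.interval.end) == (99, 100)
    assert (v.interval.ref_allele, v.interval.alt_allele) == ("A", "T")


def test_maf_round_trip_reproduces_rows(tmp_path):
    """Converting to internal coordinates and back reproduces the MAF rows."""
    rows = ("BRAF\t7\t100\t100\tA\tT\tMissense_Mutation\tS1\n"
            "KRAS\t12\t200\t202\tACG\t-\tFrame_Shift_Del\tS2\n"
            "EGFR\t7\t300\t301\t-\tTTT\tIn_Frame_Ins\tS3\n")
    path = tmp_path / "in.maf"
    path.write_text(_MAF_HEADER + rows)
    variants = read_maf(path)
    out = tmp_path / "out.maf"
    write_maf(variants, out)
    assert out.read_text() == _MAF_HEADER + rows


def test_maf_dash_allele_becomes_empty(tmp_path):
    path = tmp_path / "del.maf"
    path.write_text(_MAF_HEADER + "KRAS\t12\t200\t202\tACG\t-\tFrame_Shift_Del\tS1\n")
    (v,) = read_maf(path)
    assert v.interval.alt_allele == ""
    assert (v.interval.start, v.interval.end) == (199, 202)


def test_empty_maf_with_header_is_fine(tmp_path):
    path = tmp_path / "empty.maf"
    path.write_text(_MAF_HEADER)
    assert read_maf(path) == []


def test_maf_missing_column_raises_listing_names(tmp_path):
    path = tmp_path / "bad.maf"
    path.write_text("Hugo_Symbol\tChromosome\n")
    with pytest.raises(FormatError) as err:
        read_maf(path)
    assert "Start_Position" in str(err.value)


@pytest.mark.parametrize("consequence,kept", [
    ("Silent", False), ("Intron", False), ("3'UTR", False),
    ("Splice_Region", False), ("3′Flank", False),  # typographic prime
    ("Missense_Mutation", True), ("Nonsense_Mutation", True),
    ("Frame_Shift_Del", True), ("Splice_Site", True),
])
def test_consequence_filter_cases(tmp_path, consequence, kept):
    path = tmp_path / "c.maf"
    path.write_text(_MAF_HEADER + f"BRAF\t7\t100\t100\tA\tT\t{consequence}\tS1\n")
    retained, excluded = filter_by_consequence(read_maf(path))
    assert bool(retained) is kept and bool(excluded) is not kept


def test_consequence_filter_is_exact_partition_and_idempotent(cohort_paths):
    maf, _ = cohort_paths
    variants = read_maf(maf)
    retained, excluded = filter_by_consequence(variants)
    assert len(retained) + len(excluded) == len(variants)
    assert sorted(map(id, retained + excluded)) == sorted(map(id, variants))
    retained2, excluded2 = filter_by_consequence(retained)
    assert retained2 == retained and excluded2 == []


def test_clinical_reader_maps_oncotree_and_flags_ambiguity(tmp_path):
    path = tmp_path / "clin.txt"
    path.write_text("SAMPLE_ID\tPATIENT_ID\tONCOTREE_CODE\n"
                    "S1\tP1\tLUAD\nS2\tP2\tMIXED\nS3\tP3\tUNKNOWNCODE\n")
    samples = read_clinical(path, load_oncotree_map())
    by_id = {s.sample_id: s for s in samples}
    assert by_id["S1"].doid == "DOID:3910" and not by_id["S1"].needs_review
    assert by_id["S2"].doid is not None and by_id["S2"].needs_review
    assert by_id["S3"].doid is None


def test_clinical_duplicate_sample_id_rejected(tmp_path):
    path = tmp_path / "dup.txt"
    path.write_text("SAMPLE_ID\tPATIENT_ID\tONCOTREE_CODE\n"
                    "S1\tP1\tLUAD\nS1\tP2\tBRCA\n")
    with pytest.raises(FormatError):
        read_clinical(path)
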