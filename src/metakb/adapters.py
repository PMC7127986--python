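"""File-based readers for the six knowledgebase dialects and cohort files.

Each knowledgebase ships its interpretations in its own record shape: one
per-variant-biomarker TSV (CGI) and five JSON record lists (CIViC, OncoKB,
JAX-CKB, MolecularMatch, PMKB). Readers preserve each record's payload
verbatim as a :class:`~metakb.model.RawInterpretation`; malformed records go
to a rejects report instead of aborting the run. A per-dialect extractor then
pulls the five interpretation elements (gene, variant, disease, drugs,
evidence) out of the payload for harmonization.

Cohort input follows the standard mutation-annotation format (MAF, 1-based
inclusive coordinates, "-" for absent alleles) plus a clinical sample TSV;
both are converted to internal conventions on read.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Optional

from .model import GenomicInterval, RawInterpretation, Source


class FormatError(ValueError):
    """Input file does not have the expected dialect shape."""


@dataclass(frozen=True)
class RejectedRecord:
    index: int
    reason: str
    payload: dict


@dataclass
class ReadResult:
    records: list[RawInterpretation]
    rejects: list[RejectedRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# required payload fields per dialect (beyond the record identifier)
_TSV_DIALECTS = {Source.CGI}
_REQUIRED = {
    Source.CGI: ("Gene", "Alteration", "Evidence_Level"),
    Source.CIVIC: ("gene", "variant", "evidence_level"),
    Source.ONCOKB: ("gene", "alteration", "level"),
    Source.JAX_CKB: ("gene", "variant", "approvalStatus"),
    Source.MMATCH: ("mutations", "tier"),
    Source.PMKB: ("gene", "variant", "tier"),
}
_ID_FIELD = {
    Source.CGI: "Record_ID",
    Source.CIVIC: "id",
    Source.ONCOKB: "id",
    Source.JAX_CKB: "id",
    Source.MMATCH: "id",
    Source.PMKB: "id",
}


def read_source_dump(path, dialect: Source | str) -> ReadResult:
    """Read one knowledgebase dump into verbatim raw interpretations.

    Malformed records (missing identifier or required fields) are collected
    into ``rejects``, never silently dropped. A file whose overall shape does
    not match the dialect raises :class:`FormatError` naming the first
    offending record.
    """
    source = Source.coerce(dialect)
    if source in _TSV_DIALECTS:
        payloads = _read_tsv_payloads(path, source)
    else:
        payloads = _read_json_payloads(path, source)

    result = ReadResult([])
    id_field, required = _ID_FIELD[source], _REQUIRED[source]
    for i, payload in enumerate(payloads):
        record_id = payload.get(id_field)
        if record_id in (None, ""):
            result.rejects.append(RejectedRecord(
                i, f"missing required identifier field {id_field!r}", payload))
            continue
        missing = [k for k in required if payload.get(k) in (None, "")]
        if missing:
            result.rejects.append(RejectedRecord(
                i, f"missing required fields: {', '.join(missing)}", payload))
            continue
        result.records.append(RawInterpretation(source, str(record_id), payload))
    return result


def _read_tsv_payloads(path, source: Source) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or len(reader.fieldnames) < 2:
            raise FormatError(
                f"{source.value} dump at {path} is not a tab-separated table")
        return [dict(row) for row in reader]


def _read_json_payloads(path, source: Source) -> list[dict]:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{source.value} dump at {path} is not JSON: {exc}")
    if not isinstance(data, list):
        raise FormatError(
            f"{source.value} dump at {path}: expected a JSON list of records, "
            f"got {type(data).__name__}")
    for i, rec in enumerate(data):
        if not isinstance(rec, dict):
            raise FormatError(
                f"{source.value} dump at {path}: record {i} is not an object")
    return data


def write_source_dump(records, path, dialect: Source | str) -> None:
    """Write raw interpretations back in their dialect shape (round-trips)."""
    source = Source.coerce(dialect)
    payloads = [r.payload for r in records]
    if source in _TSV_DIALECTS:
        fieldnames: list[str] = []
        for p in payloads:
            for k in p:
                if k not in fieldnames:
                    fieldnames.append(k)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
            writer.writeheader()
            writer.writerows(payloads)
    else:
        with open(path, "w") as fh:
            json.dump(payloads, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Element extraction per dialect


@dataclass(frozen=True)
class ExtractedFields:
    """The five interpretation elements pulled from one raw payload."""

    gene: str
    variant_name: str
    explicit: Optional[GenomicInterval]
    disease: str
    drugs: Optional[list[str]]  # None where the dialect has no drug concept
    evidence_code: str
    direction_phrase: str
    documents: tuple[str, ...]


def interval_from_1based(assembly, chromosome, start, end, ref, alt
                         ) -> GenomicInterval:
    """Convert 1-based inclusive coordinates with "-" alleles to internal form."""
    start, end = int(start), int(end)
    ref = "" if ref in (None, "", "-") else str(ref).upper()
    alt = "" if alt in (None, "", "-") else str(alt).upper()
    if not ref and alt:  # insertion after base `start`
        return GenomicInterval(assembly, str(chromosome), start, start, "", alt)
    return GenomicInterval(assembly, str(chromosome), start - 1, end, ref, alt)


def _coords_or_none(c: Optional[dict], keys=("chromosome", "start", "stop",
                                             "reference_bases", "variant_bases")
                    ) -> Optional[GenomicInterval]:
    if not c or c.get("start") in (None, ""):
        return None
    return interval_from_1based(
        c.get("assembly", "GRCh37"), c[keys[0]], c[keys[1]], c[keys[2]],
        c.get(keys[3]), c.get(keys[4]))


def _split_docs(text: str, sep: str = "|") -> tuple[str, ...]:
    return tuple(d.strip() for d in (text or "").split(sep) if d.strip())


def extract_fields(raw: RawInterpretation) -> ExtractedFields:
    """Dispatch to the dialect-specific element extractor."""
    return _EXTRACTORS[raw.source](raw.payload)


def _extract_cgi(p: dict) -> ExtractedFields:
    return ExtractedFields(
        gene=p.get("Gene", ""),
        variant_name=p.get("Alteration", ""),
        explicit=None,
        disease=p.get("Primary_Tumor_Type", ""),
        drugs=[p["Drug"]] if p.get("Drug") else [],
        evidence_code=p.get("Evidence_Level", ""),
        direction_phrase=p.get("Association", ""),
        documents=_split_docs(p.get("Source", "")),
    )


def _extract_civic(p: dict) -> ExtractedFields:
    variant = p.get("variant") or {}
    disease = p.get("disease") or {}
    src = p.get("source") or {}
    docs = []
    if src.get("citation_id"):
        kind = src.get("type", "PubMed")
        docs.append(("PMID: " if kind == "PubMed" else "") + str(src["citation_id"]))
    # evidence_level like "Level B, 2-star": the star rating is curation trust,
    # not an evidence level; strip it before mapping
    code = (p.get("evidence_level") or "").split(",")[0].strip()
    return ExtractedFields(
        gene=(p.get("gene") or {}).get("name", ""),
        variant_name=variant.get("name", ""),
        explicit=_coords_or_none(variant.get("coordinates")),
        disease=disease.get("name", ""),
        drugs=[d["name"] for d in p.get("drugs", []) if d.get("name")],
        evidence_code=code,
        direction_phrase=" ".join(x for x in (p.get("evidence_direction"),
                                              p.get("clinical_significance")) if x),
        documents=tuple(docs),
    )


def _extract_oncokb(p: dict) -> ExtractedFields:
    docs = ["PMID: " + str(x) for x in p.get("pmids", [])]
    docs += [str(x) for x in p.get("dois", [])]
    return ExtractedFields(
        gene=p.get("gene", ""),
        variant_name=p.get("alteration", ""),
        explicit=None,
        disease=p.get("cancerType", ""),
        drugs=[p["drugs"]] if p.get("drugs") else [],
        evidence_code=p.get("level", ""),
        direction_phrase=p.get("direction", ""),
        documents=tuple(docs),
    )


def _extract_jax(p: dict) -> ExtractedFields:
    refs = []
    for r in p.get("references", []):
        if r.get("pubMedId"):
            refs.append("PMID: " + str(r["pubMedId"]))
        elif r.get("doi"):
            refs.append(str(r["doi"]))
    therapy = (p.get("therapy") or {}).get("therapyName", "")
    return ExtractedFields(
        gene=(p.get("gene") or {}).get("geneSymbol", ""),
        variant_name=(p.get("variant") or {}).get("name", ""),
        explicit=None,
        disease=(p.get("indication") or {}).get("name", ""),
        drugs=[therapy] if therapy else [],
        evidence_code=p.get("approvalStatus", ""),
        direction_phrase=p.get("responseType", ""),
        documents=tuple(refs),
    )


def _extract_mmatch(p: dict) -> ExtractedFields:
    mut = (p.get("mutations") or [{}])[0]
    loc = mut.get("grch37_location")
    explicit = None
    if loc:
        explicit = interval_from_1based(
            "GRCh37", loc["chromosome"], loc["start"], loc["stop"],
            loc.get("ref"), loc.get("alt"))
    return ExtractedFields(
        gene=mut.get("geneSymbol", ""),
        variant_name=mut.get("name", ""),
        explicit=explicit,
        disease=p.get("condition", ""),
        drugs=[p["therapy"]] if p.get("therapy") else [],
        evidence_code=p.get("tier", ""),
        direction_phrase=p.get("direction", ""),
        documents=tuple(str(s).strip() for s in p.get("sources", [])),
    )


def _extract_pmkb(p: dict) -> ExtractedFields:
    variant = p.get("variant") or {}
    explicit = None
    if variant.get("start") not in (None, ""):
        explicit = interval_from_1based(
            variant.get("assembly", "GRCh37"), variant["chromosome"],
            variant["start"], variant["end"], variant.get("ref"),
            variant.get("alt"))
    return ExtractedFields(
        gene=(p.get("gene") or {}).get("name", ""),
        variant_name=variant.get("name", ""),
        explicit=explicit,
        disease=(p.get("tumor") or {}).get("name", ""),
        drugs=None,  # PMKB has no drug concept
        evidence_code=p.get("tier", ""),
        direction_phrase="",
        documents=tuple("PMID: " + str(c) for c in p.get("citations", [])),
    )


_EXTRACTORS = {
    Source.CGI: _extract_cgi,
    Source.CIVIC: _extract_civic,
    Source.ONCOKB: _extract_oncokb,
    Source.JAX_CKB: _extract_jax,
    Source.MMATCH: _extract_mmatch,
    Source.PMKB: _extract_pmkb,
}


# ---------------------------------------------------------------------------
# Cohort files (MAF + clinical samples)


@dataclass(frozen=True)
class CohortVariant:
    sample_id: str
    gene_symbol: str
    interval: GenomicInterval
    consequence: str
    protein_change: Optional[str] = None


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    patient_id: str
    oncotree_code: str
    doid: Optional[str] = None
    needs_review: bool = False


MAF_COLUMNS = ("Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
               "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
               "Tumor_Sample_Barcode")

#: Consequence classes treated as low predicted impact and excluded from
#: matching (everything else is retained).
EXCLUDED_CONSEQUENCES = frozenset({
    "Silent", "3'Flank", "3'UTR", "5'Flank", "5'UTR", "Intron", "Splice_Region",
})

_PRIME = str.maketrans({"′": "'"})  # typographic prime -> ASCII apostrophe


def _norm_consequence(c: str) -> str:
    return (c or "").translate(_PRIME).strip()


def read_maf(path, assembly: str = "GRCh37") -> list[CohortVariant]:
    """Read a MAF file; coordinates convert 1-based inclusive -> 0-based
    half-open, alleles are uppercased and "-" maps to the empty string."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in MAF_COLUMNS if c not in cols]
        if missing:
            raise FormatError(
                f"MAF at {path} is missing required columns: {', '.join(missing)}")
        variants = []
        for row in reader:
            interval = interval_from_1based(
                assembly, row["Chromosome"], row["Start_Position"],
                row["End_Position"], row["Reference_Allele"],
                row["Tumor_Seq_Allele2"])
            variants.append(CohortVariant(
                sample_id=row["Tumor_Sample_Barcode"],
                gene_symbol=row["Hugo_Symbol"],
                interval=interval,
                consequence=_norm_consequence(row["Variant_Classification"]),
                protein_change=row.get("HGVSp_Short") or None,
            ))
    return variants


def write_maf(variants, path) -> None:
    """Write cohort variants back to MAF conventions (inverse of read_maf)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(MAF_COLUMNS)
        for v in variants:
            iv = v.interval
            if iv.ref_allele == "" and iv.alt_allele:  # insertion
                start, end = iv.start, iv.start + 1
            else:
                start, end = iv.start + 1, iv.end
            writer.writerow([
                v.gene_symbol, iv.chromosome, start, end,
                iv.ref_allele or "-", iv.alt_allele or "-",
                v.consequence, v.sample_id,
            ])


def read_clinical(path, oncotree_map=None) -> list[CohortSample]:
    """Read the clinical sample TSV (SAMPLE_ID, PATIENT_ID, ONCOTREE_CODE).

    With an oncotree -> ontology map supplied, each sample gets a mapped
    disease identifier; one-to-many codes take the first mapping and carry a
    needs_review flag.
    """
    samples = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in ("SAMPLE_ID", "PATIENT_ID", "ONCOTREE_CODE")
                   if c not in cols]
        if missing:
            raise FormatError(
                f"clinical file at {path} missing columns: {', '.join(missing)}")
        for row in reader:
            sid = row["SAMPLE_ID"]
            if sid in seen:
                raise FormatError(f"duplicate SAMPLE_ID {sid!r} in {path}")
            seen.add(sid)
            doid, review = None, False
            if oncotree_map:
                hits = oncotree_map.get(row["ONCOTREE_CODE"], [])
                if hits:
                    doid, review = hits[0]
                    review = review or len(hits) > 1
            samples.append(CohortSample(sid, row["PATIENT_ID"],
                                        row["ONCOTREE_CODE"], doid, review))
    return samples


def filter_by_consequence(variants) -> tuple[list[CohortVariant], list[CohortVariant]]:
    """Partition variants into (retained, excluded) by predicted impact.

    The exclusion set covers silent and non-coding classes; the partition is
    exact and idempotent on its retained output.
    """
    retained, excluded = [], []
    for v in variants:
        (excluded if _norm_consequence(v.consequence) in EXCLUDED_CONSEQUENCES
         else retained).append(v)
    return retained, excluded
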