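"""Synthetic fixture generation: knowledgebase dumps and patient cohorts.

The generator manufactures inputs with the statistical structure observed
across real interpretation knowledgebases — most variants unique to one
source, genes shared far more often than publications, per-source evidence
vocabularies — so that every downstream stage (adapters, harmonizers, match
engine, consensus statistics) is exercisable offline at any scale.

Two kinds of content are produced:

* planted *shared* elements: the same underlying variant/disease/drug
  expressed in each source's own spelling (label decorations, ontology
  synonyms, brand names). These are recoverable as identical keys only
  after harmonization, which is what the consensus statistics measure.
* per-source *unique* elements, plus categorical concepts ("oncogenic
  mutation", "amplification") in the sources that use them.

By default the dumps embed the bundled ERBB2 exon-20 duplication records
(the worked example spanning all six sources) verbatim. Cohorts are written
as a MAF plus clinical sample TSV, with a configurable fraction of samples
left without any qualifying variant after consequence filtering; those
samples stay in every downstream denominator.

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .adapters import write_source_dump
from .drugs import split_combination
from .model import GenomicInterval, RawInterpretation, Source
from .resources import (load_coordinate_lookup, load_gene_loci,
                        load_table2_rows)

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class FixtureConfig:
    """Knobs for the synthetic six-source knowledgebase dumps."""

    records_per_source: int = 40
    categorical_fraction: float = 0.15
    sharing_fraction: float = 0.30
    include_erbb2: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.categorical_fraction <= 1):
            raise ValueError("categorical_fraction must be in [0,1]")
        if not (0 <= self.sharing_fraction <= 1):
            raise ValueError("sharing_fraction must be in [0,1]")
        if self.records_per_source < 0:
            raise ValueError("record counts must be >= 0")


@dataclass
class CohortConfig:
    """Knobs for the synthetic patient cohort (MAF + clinical TSV)."""

    n_samples: int = 1000
    zero_variant_fraction: float = 0.12
    mean_variants: float = 3.0
    hotspot_fraction: float = 0.45
    seed: int = 0


# ---------------------------------------------------------------------------
# Spelling pools (shared elements expressed per-source)

_DISEASE_SPELLINGS = [
    ("breast cancer", ["breast cancer", "neoplasm of breast", "mammary cancer"]),
    ("lung cancer", ["lung cancer", "neoplasm of lung", "lung cancer"]),
    ("non-small cell lung carcinoma",
     ["NSCLC", "non-small cell lung carcinoma", "non-small cell lung cancer"]),
    ("colorectal cancer", ["colorectal cancer", "CRC", "colorectal cancer"]),
    ("melanoma", ["melanoma", "melanoma", "melanoma"]),
    ("chronic lymphocytic leukemia",
     ["CLL", "chronic lymphocytic leukemia", "CLL"]),
    ("lung adenocarcinoma",
     ["lung adenocarcinoma", "adenocarcinoma of lung", "lung adenocarcinoma"]),
]

_DRUG_SPELLINGS = [
    ("trastuzumab", ["trastuzumab", "herceptin"]),
    ("vemurafenib", ["vemurafenib", "zelboraf"]),
    ("lapatinib", ["lapatinib", "tykerb"]),
    ("gefitinib", ["gefitinib", "iressa"]),
    ("erlotinib", ["erlotinib", "tarceva"]),
    ("imatinib", ["imatinib", "gleevec"]),
    ("afatinib", ["afatinib", "gilotrif"]),
    ("dabrafenib", ["dabrafenib", "tafinlar"]),
]

# one source occasionally refers to a gene by a retired/alias symbol
_GENE_ALIAS_SPELLING = {"TP53": "P53", "EGFR": "ERBB"}

_EVIDENCE_VOCAB = {
    Source.CGI: ["Clinical practice", "Clinical trials III-IV",
                 "Clinical trials I-II", "Case reports", "Early trials",
                 "Preclinical data"],
    Source.CIVIC: ["Level A", "Level B", "Level C", "Level D"],
    Source.JAX_CKB: ["Guideline", "Phase III", "Clinical study", "Phase I",
                     "Phase II", "Preclinical"],
    Source.MMATCH: ["Level 1A", "Level 1B", "Level 2C", "Level 2D"],
    Source.ONCOKB: ["Level 1", "Level 2A", "Level 3A", "Level 2B", "Level 3B",
                    "Level 4"],
    Source.PMKB: ["Tier 1", "Tier 2"],
}

_CATEGORICAL_LABELS = {
    Source.CGI: ["oncogenic mutation"],
    Source.ONCOKB: ["Oncogenic Mutations", "Amplification"],
    Source.JAX_CKB: ["amplification", "overexpression"],
    Source.CIVIC: ["AMPLIFICATION"],
    Source.MMATCH: ["amplification"],
    Source.PMKB: ["mutation"],
}

_SOURCE_ORDER = [Source.CGI, Source.CIVIC, Source.JAX_CKB, Source.MMATCH,
                 Source.ONCOKB, Source.PMKB]

_DUMP_FILENAMES = {
    Source.CGI: "cgi_biomarkers.tsv",
    Source.CIVIC: "civic_evidence.json",
    Source.JAX_CKB: "jax_ckb.json",
    Source.MMATCH: "molecularmatch.json",
    Source.ONCOKB: "oncokb.json",
    Source.PMKB: "pmkb_interpretations.json",
}


def _variant_spelling(source: Source, gene: str, label: str) -> str:
    return {
        Source.CGI: f"{gene}:{label}",
        Source.CIVIC: f"p.{label}",
        Source.JAX_CKB: f"{gene} {label}",
        Source.MMATCH: f"{gene} {label} (GRCh37)",
        Source.ONCOKB: label,
        Source.PMKB: f"{gene}-{label}",
    }[source]


def _explicit_coords(source: Source, interval: GenomicInterval):
    """Dialects that carry explicit coordinates; 1-based inclusive payload."""
    if source not in (Source.CIVIC, Source.MMATCH, Source.PMKB):
        return None
    if interval.ref_allele == "" and interval.alt_allele:
        start, stop = interval.start, interval.start + 1
    else:
        start, stop = interval.start + 1, interval.end
    return {
        "chromosome": interval.chromosome,
        "start": start,
        "stop": stop,
        "ref": interval.ref_allele or "-",
        "alt": interval.alt_allele or "-",
        "assembly": interval.assembly,
    }


def _make_payload(source: Source, record_id: str, gene: str, variant: str,
                  coords, disease: str, drug: str, code: str,
                  direction: str, docs: list[str]) -> dict:
    """Build one dialect-shaped payload."""
    if source is Source.CGI:
        return {
            "Record_ID": record_id, "Gene": gene, "Alteration": variant,
            "Primary_Tumor_Type": disease, "Drug": drug,
            "Evidence_Level": code,
            "Association": {"supports": "Responsive",
                            "does_not_support": "No Responsive",
                            "conflicting": "Resistant"}.get(direction, "Responsive"),
            "Source": "|".join(docs),
        }
    if source is Source.CIVIC:
        pmid = docs[0] if docs else ""
        is_pmid = pmid.upper().startswith("PMID")
        return {
            "id": record_id,
            "gene": {"name": gene},
            "variant": {"name": variant,
                        "coordinates": _civic_coords(coords)},
            "disease": {"name": disease},
            "drugs": [{"name": d} for d in split_combination(drug)],
            "evidence_level": code,
            "evidence_direction": {"supports": "Supports",
                                   "does_not_support": "Does not support",
                                   "conflicting": "Conflicting"}.get(
                                       direction, "Supports"),
            "clinical_significance": "Sensitivity/Response",
            "source": {"citation_id": pmid.split(":")[-1].strip() if is_pmid
                       else pmid,
                       "type": "PubMed" if is_pmid else "ASCO"},
        }
    if source is Source.JAX_CKB:
        refs = []
        for d in docs:
            if d.upper().startswith("PMID"):
                refs.append({"pubMedId": d.split(":")[-1].strip()})
            else:
                refs.append({"doi": d})
        return {
            "id": record_id,
            "gene": {"geneSymbol": gene},
            "variant": {"name": variant},
            "indication": {"name": disease},
            "therapy": {"therapyName": drug},
            "approvalStatus": code,
            "responseType": {"supports": "sensitive",
                             "does_not_support": "no benefit",
                             "conflicting": "conflicting"}.get(direction,
                                                               "sensitive"),
            "references": refs,
        }
    if source is Source.MMATCH:
        mutation = {"geneSymbol": gene, "name": variant}
        if coords:
            mutation["grch37_location"] = {k: coords[k] for k in
                                           ("chromosome", "start", "stop",
                                            "ref", "alt")}
        return {
            "id": record_id,
            "mutations": [mutation],
            "condition": disease,
            "therapy": drug,
            "tier": code,
            "direction": {"supports": "Confers sensitivity",
                          "does_not_support": "Does not confer sensitivity",
                          "conflicting": "Conflicting"}.get(direction,
                                                            "Confers sensitivity"),
            "sources": docs,
        }
    if source is Source.ONCOKB:
        pmids = [d.split(":")[-1].strip() for d in docs
                 if d.upper().startswith("PMID")]
        dois = [d for d in docs if not d.upper().startswith("PMID")]
        return {
            "id": record_id, "gene": gene, "alteration": variant,
            "cancerType": disease, "drugs": drug, "level": code,
            "direction": {"supports": "Supports",
                          "does_not_support": "Does not support"}.get(
                              direction, "Supports"),
            "pmids": pmids, "dois": dois,
        }
    if source is Source.PMKB:
        variant_obj = {"name": variant}
        if coords:
            variant_obj.update({"chromosome": coords["chromosome"],
                                "start": coords["start"], "end": coords["stop"],
                                "ref": coords["ref"], "alt": coords["alt"],
                                "assembly": coords["assembly"]})
        return {
            "id": record_id,
            "gene": {"name": gene},
            "variant": variant_obj,
            "tumor": {"name": disease},
            "tier": code,
            "citations": [d.split(":")[-1].strip() for d in docs
                          if d.upper().startswith("PMID")],
        }
    raise ValueError(source)


def _civic_coords(coords):
    if not coords:
        return None
    return {"chromosome": coords["chromosome"], "start": coords["start"],
            "stop": coords["stop"], "reference_bases": coords["ref"],
            "variant_bases": coords["alt"], "assembly": coords["assembly"]}


def table2_raw_records() -> list[RawInterpretation]:
    """The bundled ERBB2 exon-20 duplication rows as per-dialect raw records."""
    rows = load_table2_rows()
    records = []
    counters: dict[Source, int] = {}
    for row in rows:
        source = Source.coerce(row["resource"])
        counters[source] = counters.get(source, 0) + 1
        record_id = f"{source.value.lower()}-erbb2-{counters[source]}"
        docs = [d.strip() for d in row["documents"].split("|") if d.strip()]
        payload = _make_payload(
            source, record_id, "ERBB2", row["variant"], None, row["disease"],
            row["drugs"], row["evidence"], row["direction"], docs)
        records.append(RawInterpretation(source, record_id, payload))
    return records


# ---------------------------------------------------------------------------
# Knowledgebase dump generation


def generate_synthetic_kbs(config: FixtureConfig, outdir) -> dict[Source, Path]:
    """Write six dialect dumps; returns {source: path}.

    Deterministic for a given config; with sharing fraction 0 (and the ERBB2
    records disabled) the planted variant sets are pairwise disjoint.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    lookup = load_coordinate_lookup()
    loci = load_gene_loci()
    # the recurrent hotspots every source curates, in display case (lookup
    # keys are lower-cased)
    display = {(g, l.lower()): l for g, l in
               [("BRAF", "V600E"), ("BRAF", "V600K"), ("KRAS", "G12D"),
                ("KRAS", "G12C"), ("KRAS", "G12V"), ("PIK3CA", "E545K"),
                ("PIK3CA", "H1047R"), ("EGFR", "L858R"), ("EGFR", "T790M"),
                ("NRAS", "Q61K"), ("TP53", "R175H"), ("ALK", "F1174L")]}
    shared_variants = sorted(display)

    n = config.records_per_source
    n_shared = round(config.sharing_fraction * n)
    n_categorical = round(config.categorical_fraction * n)
    shared_pubs = [f"PMID: {7000001 + i}" for i in range(10)]
    unique_pub_counter = [0]

    def next_unique_pub() -> str:
        unique_pub_counter[0] += 1
        return f"PMID: {9000000 + unique_pub_counter[0]}"

    paths: dict[Source, Path] = {}
    erbb2_records = table2_raw_records() if config.include_erbb2 else []
    genes_sorted = sorted(g for g in loci if not g.startswith("GENE"))

    for src_index, source in enumerate(_SOURCE_ORDER):
        records: list[RawInterpretation] = []
        # each source curates its own slice of the gene universe (plus the
        # shared hotspot genes), so most genes stay unique to one source
        lo = (src_index * 6) % max(1, len(genes_sorted) - 12)
        source_genes = genes_sorted[lo: lo + 12] or genes_sorted
        vocab = _EVIDENCE_VOCAB[source]
        weights = np.linspace(1.0, 2.0, len(vocab))
        weights /= weights.sum()
        for i in range(n):
            record_id = f"{source.value.lower()}-{i + 1}"
            code = vocab[int(rng.choice(len(vocab), p=weights))]
            direction = "supports" if rng.random() > 0.15 else "does_not_support"
            docs = [shared_pubs[int(rng.integers(len(shared_pubs)))]
                    if rng.random() < 0.15 else next_unique_pub()]

            if i < n_shared:  # planted shared interpretation
                gene, label_lc = shared_variants[i % len(shared_variants)]
                label = display.get((gene, label_lc), label_lc)
                variant = _variant_spelling(source, gene, label)
                interval = lookup[(gene, label_lc)]
                coords = _explicit_coords(source, interval)
                canon, spellings = _DISEASE_SPELLINGS[i % len(_DISEASE_SPELLINGS)]
                disease = spellings[src_index % len(spellings)]
                drug_id, drug_spellings = _DRUG_SPELLINGS[i % len(_DRUG_SPELLINGS)]
                drug = drug_spellings[src_index % len(drug_spellings)]
                gene_spelling = gene
                if src_index == 2 and gene in _GENE_ALIAS_SPELLING:
                    gene_spelling = _GENE_ALIAS_SPELLING[gene]
            elif i < n_shared + n_categorical:  # categorical concept
                if source is Source.CGI:
                    # CGI's categorical concepts come with an expansion
                    # catalog; keep them on the genes that catalog covers
                    gene = ["BRAF", "KRAS", "PIK3CA", "EGFR"][i % 4]
                else:
                    gene = source_genes[int(rng.integers(len(source_genes)))]
                labels = _CATEGORICAL_LABELS[source]
                variant = labels[int(rng.integers(len(labels)))]
                coords = None
                disease = _DISEASE_SPELLINGS[
                    int(rng.integers(len(_DISEASE_SPELLINGS)))][0]
                drug = _DRUG_SPELLINGS[
                    int(rng.integers(len(_DRUG_SPELLINGS)))][1][0]
                gene_spelling = gene
            else:  # unique to this source
                gene = source_genes[int(rng.integers(len(source_genes)))]
                locus = loci[gene]
                pos = locus.start + 50 + src_index * 2000 + (i % 600) * 3
                ref = reference.base_at(locus.assembly, locus.chromosome, pos)
                alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
                interval = GenomicInterval(locus.assembly, locus.chromosome,
                                           pos, pos + 1, ref, alt)
                variant = f"{source.value}var{i}"
                coords = _explicit_coords(source, interval)
                disease = _DISEASE_SPELLINGS[
                    int(rng.integers(len(_DISEASE_SPELLINGS)))][0]
                drug = _DRUG_SPELLINGS[
                    int(rng.integers(len(_DRUG_SPELLINGS)))][1][0]
                gene_spelling = gene

            payload = _make_payload(source, record_id, gene_spelling, variant,
                                    coords, disease, drug, code, direction,
                                    docs)
            records.append(RawInterpretation(source, record_id, payload))

        records.extend(r for r in erbb2_records if r.source is source)
        path = outdir / _DUMP_FILENAMES[source]
        write_source_dump(records, path, source)
        paths[source] = path
    return paths


# ---------------------------------------------------------------------------
# Cohort generation

_RETAINED_CONSEQUENCES = ["Missense_Mutation", "Nonsense_Mutation",
                          "Frame_Shift_Del", "In_Frame_Ins", "Splice_Site"]
_EXCLUDED_CONSEQUENCES = ["Silent", "Intron", "3'UTR", "5'Flank",
                          "Splice_Region"]
_ONCOTREE_CODES = ["LUAD", "NSCLC", "BRCA", "IDC", "ILC", "COADREAD", "SKCM",
                   "CLL", "ALL", "BLCA", "HGSOC", "BONE", "UNK"]


def generate_synthetic_cohort(config: CohortConfig, outdir
                              ) -> tuple[Path, Path]:
    """Write a synthetic MAF + clinical sample TSV; returns their paths.

    A configurable fraction of samples (default 12%) carries no qualifying
    variant after consequence filtering: they either have no calls at all or
    only calls in excluded consequence classes. Every sample appears in the
    clinical file. Byte-identical across runs for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    lookup = load_coordinate_lookup()
    loci = load_gene_loci()
    hotspots = sorted(
        ((gene, label, iv) for (gene, label), iv in lookup.items()
         if iv.alt_allele and iv.end > iv.start),
        key=lambda t: (t[0], t[1]))
    genes_sorted = sorted(g for g in loci if not g.startswith("GENE"))

    maf_path = outdir / "data_mutations_extended.txt"
    clin_path = outdir / "data_clinical_sample.txt"
    maf_rows = []
    clin_rows = []
    for i in range(config.n_samples):
        sample_id = f"SAMP-{i + 1:05d}"
        patient_id = f"PAT-{i + 1:05d}"
        code = _ONCOTREE_CODES[int(rng.integers(len(_ONCOTREE_CODES)))]
        clin_rows.append((sample_id, patient_id, code))

        zero_qualifying = rng.random() < config.zero_variant_fraction
        if zero_qualifying:
            # no calls at all, or only low-impact calls
            n_calls = int(rng.integers(0, 3))
            consequences = [_EXCLUDED_CONSEQUENCES[
                int(rng.integers(len(_EXCLUDED_CONSEQUENCES)))]
                for _ in range(n_calls)]
            hot = [False] * n_calls
        else:
            n_calls = max(1, int(rng.poisson(config.mean_variants)))
            consequences = [_RETAINED_CONSEQUENCES[
                int(rng.integers(len(_RETAINED_CONSEQUENCES)))]
                for _ in range(n_calls)]
            hot = [rng.random() < config.hotspot_fraction
                   for _ in range(n_calls)]

        for k in range(n_calls):
            if hot[k]:
                gene, _, iv = hotspots[int(rng.integers(len(hotspots)))]
                start, end = iv.start + 1, iv.end
                ref, alt = iv.ref_allele, iv.alt_allele
                consequences[k] = "Missense_Mutation"
            else:
                gene = genes_sorted[int(rng.integers(len(genes_sorted)))]
                locus = loci[gene]
                pos = int(rng.integers(locus.start + 1, locus.end))
                start = end = pos + 1
                ref = "ACGT"[int(rng.integers(4))]
                alt = "ACGT"[int(rng.integers(4))]
                if alt == ref:
                    alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                iv = loci[gene]
            maf_rows.append((gene, iv.chromosome, start, end, ref, alt,
                             consequences[k], sample_id))

    with open(maf_path, "w") as fh:
        fh.write("Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\t"
                 "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
                 "Tumor_Sample_Barcode\n")
        for row in maf_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(clin_path, "w") as fh:
        fh.write("SAMPLE_ID\tPATIENT_ID\tONCOTREE_CODE\n")
        for row in clin_rows:
            fh.write("\t".join(row) + "\n")
    return maf_path, clin_path
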