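"""End-to-end harmonization: raw dialect records -> associations.

For each raw record the pipeline normalizes all five interpretation
elements — gene symbol, variant (coordinates, genomic HGVS, canonical allele
key, categorical expansion), disease (ontology + TopNode), drugs (synonym
chain) and evidence (AMP/ASCO/CAP level + direction) — and assembles a
validated :class:`~metakb.model.Association`. Records whose evidence code
cannot be mapped, or whose assembled association violates a model invariant,
go to a rejects report; they never abort the run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Optional

from . import reference
from .adapters import RejectedRecord, extract_fields, read_source_dump
from .diseases import OntologyGraph, normalize_disease
from .drugs import DrugSynonymChain, normalize_drug_list
from .evidence import EvidenceMap, EvidenceMappingError, map_evidence
from .genes import GeneTable, normalize_gene
from .model import (Association, Direction, Evidence, GenomicInterval,
                    RawInterpretation, Source, VariantCategory, VariantNorm,
                    validate_association)
from .resources import (data_path, load_accessions, load_coordinate_lookup,
                        load_drug_chain, load_evidence_map, load_gene_loci,
                        load_gene_table, load_ontology, load_shorthand)
from .stats import normalize_document
from .variants import (AccessionLookupError, ReferenceMismatchError,
                       canonical_allele_key, assemble_hgvs_g,
                       infer_coordinates)

# Ordered (phrase prefix -> direction) rules per dialect; free-text direction
# phrases outside the table harmonize to "unstated".
_DIRECTION_RULES: dict[Source, list[tuple[str, Direction]]] = {
    Source.CIVIC: [
        ("does not support", Direction.DOES_NOT_SUPPORT),
        ("conflicting", Direction.CONFLICTING),
        ("supports", Direction.SUPPORTS),
    ],
    Source.ONCOKB: [
        ("does not support", Direction.DOES_NOT_SUPPORT),
        ("supports", Direction.SUPPORTS),
    ],
    Source.JAX_CKB: [
        ("conflicting", Direction.CONFLICTING),
        ("no benefit", Direction.DOES_NOT_SUPPORT),
        ("decreased response", Direction.DOES_NOT_SUPPORT),
        ("predicted sensitive", Direction.SUPPORTS),
        ("predicted resistant", Direction.SUPPORTS),
        ("sensitive", Direction.SUPPORTS),
        ("resistant", Direction.SUPPORTS),
    ],
    Source.CGI: [
        ("not responsive", Direction.DOES_NOT_SUPPORT),
        ("no responsive", Direction.DOES_NOT_SUPPORT),
        ("responsive", Direction.SUPPORTS),
        ("resistant", Direction.SUPPORTS),
    ],
    Source.MMATCH: [
        ("does not", Direction.DOES_NOT_SUPPORT),
        ("confers sensitivity", Direction.SUPPORTS),
        ("confers resistance", Direction.SUPPORTS),
        ("supports", Direction.SUPPORTS),
    ],
    Source.PMKB: [],
}


def harmonize_direction(source: Source, phrase: str) -> Direction:
    p = (phrase or "").strip().lower()
    for prefix, direction in _DIRECTION_RULES.get(source, []):
        if p.startswith(prefix):
            return direction
    return Direction.UNSTATED


def load_expansion_table(path=None) -> dict[tuple[Source, str, str], list[str]]:
    """(source, gene, lower-cased label) -> constituent allele labels."""
    table: dict[tuple[Source, str, str], list[str]] = {}
    with open(path or data_path("categorical_expansion.tsv"), newline="") as fh:
        for row in csv.DictReader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"):
            key = (Source.coerce(row["source"]), row["gene"],
                   row["label"].strip().lower())
            table[key] = [a.strip() for a in row["alleles"].split("|") if a.strip()]
    return table


@dataclass
class HarmonizationContext:
    """All reference tables the pipeline needs, bundled or user-supplied."""

    gene_table: GeneTable
    ontology: OntologyGraph
    evidence_map: EvidenceMap
    drug_chain: DrugSynonymChain
    coordinate_lookup: dict[tuple[str, str], GenomicInterval]
    gene_loci: dict[str, GenomicInterval]
    accessions: dict[tuple[str, str], str]
    shorthand: dict[str, dict[str, str]] = field(default_factory=dict)
    expansion: dict[tuple[Source, str, str], list[str]] = field(default_factory=dict)
    get_slice: Callable = reference.slice_around

    @classmethod
    def default(cls) -> "HarmonizationContext":
        return cls(
            gene_table=load_gene_table(),
            ontology=load_ontology(),
            evidence_map=load_evidence_map(),
            drug_chain=load_drug_chain(),
            coordinate_lookup=load_coordinate_lookup(),
            gene_loci=load_gene_loci(),
            accessions=load_accessions(),
            shorthand=load_shorthand(),
            expansion=load_expansion_table(),
        )


def _variant_norm(name: str, interval: Optional[GenomicInterval],
                  category: VariantCategory, ctx: HarmonizationContext
                  ) -> VariantNorm:
    hgvs = key = None
    if (interval is not None and category is VariantCategory.ALLELE_SPECIFIC
            and interval.alt_allele):
        try:
            hgvs = assemble_hgvs_g(interval, ctx.accessions)
            key = canonical_allele_key(hgvs, ctx.get_slice(interval))
        except AccessionLookupError:
            hgvs = key = None
        except ReferenceMismatchError:
            key = None  # record disagrees with the reference; keep the HGVS
    return VariantNorm(name=name, interval=interval, hgvs_g=hgvs,
                       allele_key=key, category=category)


def harmonize_raw(raw: RawInterpretation, ctx: HarmonizationContext
                  ) -> Association:
    """Harmonize one raw record; raises EvidenceMappingError on unmappable
    evidence codes (callers collect these as rejects)."""
    ex = extract_fields(raw)

    gene = normalize_gene(ex.gene, ctx.gene_table)

    inference = infer_coordinates(ex.variant_name, gene, ctx.coordinate_lookup,
                                  ctx.gene_loci, explicit=ex.explicit)
    variants = [_variant_norm(ex.variant_name, inference.interval,
                              inference.category, ctx)]
    # categorical concepts expand to their member alleles where the
    # per-source expansion table says so; the categorical record is retained
    if inference.category is not VariantCategory.ALLELE_SPECIFIC and gene.symbol:
        from .variants import _norm_label  # shared label normalization
        members = ctx.expansion.get(
            (raw.source, gene.symbol, _norm_label(ex.variant_name)), [])
        for label in members:
            hit = ctx.coordinate_lookup.get((gene.symbol, label.lower()))
            if hit is not None:
                variants.append(_variant_norm(
                    label, hit, VariantCategory.ALLELE_SPECIFIC, ctx))

    disease = normalize_disease(ex.disease, ctx.ontology,
                                ctx.shorthand.get(raw.source.value))

    drugs = None
    if ex.drugs:  # PMKB extractor yields None; empty lists also stay absent
        drugs = normalize_drug_list(ex.drugs, ctx.drug_chain)

    level, tier = map_evidence(raw.source, ex.evidence_code, ctx.evidence_map)
    docs, seen = [], set()
    for doc in ex.documents:
        norm = normalize_document(doc)
        if norm not in seen:
            seen.add(norm)
            docs.append(norm)
    evidence = Evidence(
        source_level=ex.evidence_code,
        harmonized_level=level,
        tier=tier,
        direction=harmonize_direction(raw.source, ex.direction_phrase),
        documents=tuple(docs),
    )

    return Association(
        source=raw.source, record_id=raw.record_id, gene=gene,
        variants=tuple(variants), disease=disease, drugs=drugs,
        evidence=evidence, raw=raw,
    )


@dataclass
class HarmonizeResult:
    associations: list[Association]
    rejects: dict[str, list[RejectedRecord]]
    summary: dict[str, dict[str, int]]


def harmonize_dumps(dumps: dict[Source, str],
                    ctx: Optional[HarmonizationContext] = None
                    ) -> HarmonizeResult:
    """Read and harmonize a set of dialect dumps into one sorted store.

    Output ordering is deterministic (source value, record id); the summary
    carries per-source input/accepted/rejected counts.
    """
    ctx = ctx or HarmonizationContext.default()
    associations: list[Association] = []
    rejects: dict[str, list[RejectedRecord]] = {}
    summary: dict[str, dict[str, int]] = {}
    for source in sorted(dumps, key=lambda s: s.value):
        read = read_source_dump(dumps[source], source)
        src_rejects = list(read.rejects)
        n_in = len(read.records) + len(read.rejects)
        accepted = 0
        for raw in read.records:
            try:
                assoc = harmonize_raw(raw, ctx)
            except EvidenceMappingError as exc:
                src_rejects.append(RejectedRecord(-1, str(exc), raw.payload))
                continue
            violations = validate_association(assoc)
            if violations:
                src_rejects.append(
                    RejectedRecord(-1, "; ".join(violations), raw.payload))
                continue
            associations.append(assoc)
            accepted += 1
        rejects[source.value] = src_rejects
        summary[source.value] = {
            "input": n_in, "accepted": accepted, "rejected": len(src_rejects)}
    associations.sort(key=lambda a: (a.source.value, a.record_id))
    return HarmonizeResult(associations, rejects, summary)
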