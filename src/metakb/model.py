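"""Harmonized data model for somatic variant interpretations.

A clinical interpretation ("association") links a somatic variant in a gene to
a disease and, usually, a drug response, graded by an evidence level. Six
knowledgebases express this same five-element structure (gene, variant,
disease, drugs, evidence) in mutually incompatible dialects; every adapter and
harmonizer in this package produces or consumes the types defined here.

Conventions
-----------
* Genomic intervals are stored 0-based half-open internally. Dialect readers
  convert from their native convention (e.g. MAF 1-based inclusive) on ingest
  and writers convert back, so interval arithmetic is unambiguous.
* Every :class:`Association` retains the verbatim source record it was built
  from (:class:`RawInterpretation`), so no information is lost to
  harmonization and the original payload can always be displayed.
* Validation is data, not exceptions: :func:`validate_association` returns a
  list of violation descriptors and never raises on bad content.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Optional


class Source(str, enum.Enum):
    """The six constituent knowledgebases."""

    CGI = "CGI"
    CIVIC = "CIViC"
    JAX_CKB = "JAX-CKB"
    MMATCH = "MMatch"
    ONCOKB = "OncoKB"
    PMKB = "PMKB"

    @classmethod
    def coerce(cls, value: "Source | str") -> "Source":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value:
                return member
        raise ValueError(f"unknown knowledgebase source: {value!r}")


#: Sources for which a drug field exists at all (PMKB has no drug concept).
SOURCES_WITH_DRUGS = frozenset(s for s in Source if s is not Source.PMKB)

#: Root term of the cancer branch of the disease ontology.
CANCER_ROOT = "DOID:162"


@dataclass(frozen=True)
class RawInterpretation:
    """One source record exactly as read from a knowledgebase dump.

    ``payload`` is the opaque key/value record; it must round-trip through
    read/write byte-identically, so adapters never coerce or reorder it.
    """

    source: Source
    record_id: str
    payload: dict

    def to_dict(self) -> dict:
        return {
            "source": self.source.value,
            "record_id": self.record_id,
            "payload": self.payload,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RawInterpretation":
        return cls(Source.coerce(d["source"]), d["record_id"], d["payload"])


class GeneStatus(str, enum.Enum):
    NORMALIZED = "normalized"
    AMBIGUOUS_ALIAS = "ambiguous_alias"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class GeneNorm:
    """A gene symbol after lookup against the approved-symbol/alias table."""

    symbol: str = ""
    matched_via: Optional[str] = None  # "primary" | "alias"
    status: GeneStatus = GeneStatus.UNMATCHED

    def to_dict(self) -> dict:
        return {
            "symbol": self.symbol,
            "matched_via": self.matched_via,
            "status": self.status.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneNorm":
        return cls(d.get("symbol", ""), d.get("matched_via"), GeneStatus(d["status"]))


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic location, 0-based half-open, with optional alleles.

    Empty allele strings mean "not applicable / unspecified" (e.g. the alt of
    a deletion, or both alleles of a region-only record). SNVs always satisfy
    ``end == start + 1``.
    """

    assembly: str  # "GRCh37" | "GRCh38"
    chromosome: str
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self):
        if self.assembly not in ("GRCh37", "GRCh38"):
            raise ValueError(f"unknown assembly {self.assembly!r}")

    def length(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenomicInterval":
        return cls(
            d["assembly"], d["chromosome"], int(d["start"]), int(d["end"]),
            d.get("ref_allele", ""), d.get("alt_allele", ""),
        )


class VariantCategory(str, enum.Enum):
    ALLELE_SPECIFIC = "allele_specific"
    CATEGORICAL = "categorical"  # e.g. "oncogenic mutation", "exon 20 insertion"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class VariantNorm:
    """A variant after coordinate inference / HGVS assembly / allele keying."""

    name: str
    interval: Optional[GenomicInterval] = None
    hgvs_g: Optional[str] = None
    allele_key: Optional[str] = None
    category: VariantCategory = VariantCategory.UNRESOLVED

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "interval": self.interval.to_dict() if self.interval else None,
            "hgvs_g": self.hgvs_g,
            "allele_key": self.allele_key,
            "category": self.category.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariantNorm":
        iv = d.get("interval")
        return cls(
            d["name"],
            GenomicInterval.from_dict(iv) if iv else None,
            d.get("hgvs_g"),
            d.get("allele_key"),
            VariantCategory(d["category"]),
        )


class DiseaseMappingStatus(str, enum.Enum):
    MAPPED = "mapped"
    FALLBACK_CANCER = "fallback_cancer"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class DiseaseNorm:
    """A disease term mapped to the ontology and grouped to its TopNode.

    ``topnode`` is the nearest designated high-level cancer term; diseases in
    the cancer branch with no TopNode ancestor fall back to DOID:162 (cancer).
    """

    doid: Optional[str] = None
    label: str = ""
    topnode: Optional[str] = None
    mapping_status: DiseaseMappingStatus = DiseaseMappingStatus.UNMAPPED
    needs_review: bool = False

    def to_dict(self) -> dict:
        return {
            "doid": self.doid,
            "label": self.label,
            "topnode": self.topnode,
            "mapping_status": self.mapping_status.value,
            "needs_review": self.needs_review,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiseaseNorm":
        return cls(
            d.get("doid"), d.get("label", ""), d.get("topnode"),
            DiseaseMappingStatus(d["mapping_status"]), bool(d.get("needs_review", False)),
        )


@dataclass(frozen=True)
class DrugComponent:
    input_name: str
    normalized_id: Optional[str] = None
    normalized_label: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DrugComponent":
        return cls(d["input_name"], d.get("normalized_id"), d.get("normalized_label"))


@dataclass(frozen=True)
class DrugNorm:
    """One therapy, possibly a combination of several components."""

    components: tuple[DrugComponent, ...]
    is_combination: bool

    def to_dict(self) -> dict:
        return {
            "components": [c.to_dict() for c in self.components],
            "is_combination": self.is_combination,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugNorm":
        return cls(
            tuple(DrugComponent.from_dict(c) for c in d["components"]),
            bool(d["is_combination"]),
        )


class EvidenceLevel(str, enum.Enum):
    """AMP/ASCO/CAP harmonized evidence levels; A is strongest."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def rank(self) -> int:
        return "ABCD".index(self.value)

    @property
    def tier(self) -> "Tier":
        return Tier.I if self in (EvidenceLevel.A, EvidenceLevel.B) else Tier.II


class Tier(str, enum.Enum):
    I = "I"
    II = "II"


class Direction(str, enum.Enum):
    SUPPORTS = "supports"
    DOES_NOT_SUPPORT = "does_not_support"
    CONFLICTING = "conflicting"
    UNSTATED = "unstated"


@dataclass(frozen=True)
class Evidence:
    """Evidence grading: verbatim source code plus the harmonized level/tier."""

    source_level: str
    harmonized_level: EvidenceLevel
    tier: Tier
    direction: Direction = Direction.UNSTATED
    documents: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "source_level": self.source_level,
            "harmonized_level": self.harmonized_level.value,
            "tier": self.tier.value,
            "direction": self.direction.value,
            "documents": list(self.documents),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Evidence":
        return cls(
            d["source_level"], EvidenceLevel(d["harmonized_level"]), Tier(d["tier"]),
            Direction(d["direction"]), tuple(d.get("documents", ())),
        )


@dataclass(frozen=True)
class Association:
    """One harmonized interpretation: the unit of the meta-knowledgebase."""

    source: Source
    record_id: str
    gene: GeneNorm
    variants: tuple[VariantNorm, ...]
    disease: DiseaseNorm
    drugs: Optional[DrugNorm]
    evidence: Evidence
    raw: RawInterpretation

    def to_dict(self) -> dict:
        return {
            "source": self.source.value,
            "record_id": self.record_id,
            "gene": self.gene.to_dict(),
            "variants": [v.to_dict() for v in self.variants],
            "disease": self.disease.to_dict(),
            "drugs": self.drugs.to_dict() if self.drugs else None,
            "evidence": self.evidence.to_dict(),
            "raw": self.raw.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Association":
        return cls(
            Source.coerce(d["source"]),
            d["record_id"],
            GeneNorm.from_dict(d["gene"]),
            tuple(VariantNorm.from_dict(v) for v in d["variants"]),
            DiseaseNorm.from_dict(d["disease"]),
            DrugNorm.from_dict(d["drugs"]) if d.get("drugs") else None,
            Evidence.from_dict(d["evidence"]),
            RawInterpretation.from_dict(d["raw"]),
        )


class MatchClass(enum.Enum):
    """Graded variant-hit classes, most specific first.

    ``exact``: same interval and same alternate allele; ``positional``: same
    interval, different/absent allele; ``focal``: partial but reciprocally
    >10% overlap; ``regional``: any other nonzero overlap; ``gene_level``:
    matched by gene symbol only.
    """

    EXACT = 0
    POSITIONAL = 1
    FOCAL = 2
    REGIONAL = 3
    GENE_LEVEL = 4
    NONE = 5

    @property
    def rank(self) -> int:
        return self.value


# ---------------------------------------------------------------------------
# Validation


def _check_interval(iv: GenomicInterval, where: str, out: list[str]) -> None:
    if not iv.chromosome:
        out.append(f"{where}: chromosome is empty")
    if not (0 <= iv.start <= iv.end):
        out.append(f"{where}: requires 0 <= start <= end, got [{iv.start}, {iv.end})")


def validate_association(assoc: Association) -> list[str]:
    """Check every type invariant of an assembled association.

    Returns an empty list iff the association is well formed; violations are
    human-readable descriptors naming the broken rule. Never mutates or
    raises on content problems.
    """
    v: list[str] = []

    g = assoc.gene
    if (g.status is GeneStatus.NORMALIZED) != bool(g.symbol):
        v.append("gene: symbol must be non-empty iff status=normalized")

    if not assoc.variants:
        v.append("variants: at least one variant required")
    for i, var in enumerate(assoc.variants):
        where = f"variants[{i}]"
        if var.allele_key is not None and var.hgvs_g is None:
            v.append(f"{where}: allele_key present requires hgvs_g present")
        if var.category is VariantCategory.ALLELE_SPECIFIC and var.interval is None:
            v.append(f"{where}: category=allele_specific requires an interval")
        if var.interval is not None:
            _check_interval(var.interval, where, v)

    d = assoc.disease
    if d.topnode is not None and d.doid is None:
        v.append("disease: topnode present requires doid present")
    if d.mapping_status is DiseaseMappingStatus.FALLBACK_CANCER and d.topnode != CANCER_ROOT:
        v.append(f"disease: mapping_status=fallback_cancer requires topnode={CANCER_ROOT}")

    if assoc.drugs is not None:
        n = len(assoc.drugs.components)
        if assoc.drugs.is_combination != (n > 1):
            v.append("drugs: is_combination must hold iff component count > 1")
    if assoc.source is Source.PMKB and assoc.drugs is not None:
        v.append("drugs: PMKB associations must have drugs absent")

    e = assoc.evidence
    if e.harmonized_level.tier is not e.tier:
        v.append(
            "evidence: levels A,B must carry tier I and C,D tier II "
            f"(got level {e.harmonized_level.value} with tier {e.tier.value})"
        )
    if len(set(e.documents)) != len(e.documents):
        v.append("evidence: document identifiers must be unique within one Evidence")

    if assoc.raw.source is not assoc.source:
        v.append("raw: raw.source must equal association source")

    return v


# ---------------------------------------------------------------------------
# NDJSON export


def write_ndjson(associations: Iterable[Association], path) -> None:
    """Write associations as NDJSON, one object per line, stable field names."""
    with open(path, "w") as fh:
        for assoc in associations:
            fh.write(json.dumps(assoc.to_dict(), sort_keys=True) + "\n")


def read_ndjson(path) -> Iterator[Association]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Association.from_dict(json.loads(line))
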