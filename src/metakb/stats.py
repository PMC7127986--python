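"""Landscape and consensus statistics over the harmonized store.

These quantify how much the knowledgebases agree: per-element overlap across
sources (with and without harmonization), set-combination attribution for
UpSet-style summaries, disease-group proportions, interpretations per cited
publication, and two-sided Fisher exact odds-ratio tests for group
comparisons.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from scipy import stats as scipy_stats

from .adapters import extract_fields
from .model import Association, Source, SOURCES_WITH_DRUGS


# ---------------------------------------------------------------------------
# Document identifier normalization

_PMID_RE = re.compile(r"^(?:pmid[:\s]*)?(\d+)$", re.IGNORECASE)


def normalize_document(doc: str) -> str:
    """Coalesce document spellings: "PMID: 123" / "123" / "pmid:123" become
    PMID:123; DOIs are lower-cased with any leading "doi:" stripped."""
    text = (doc or "").strip()
    m = _PMID_RE.match(text)
    if m:
        return f"PMID:{m.group(1)}"
    text = re.sub(r"^doi:\s*", "", text, flags=re.IGNORECASE)
    return text.lower()


# ---------------------------------------------------------------------------
# Element sets


@dataclass
class ElementSets:
    """Per-source sets of element keys for one element kind."""

    kind: str  # gene | variant | disease | drug | publication | evidence_code
    sets: dict[str, set[str]]


def _element_keys(assoc: Association, kind: str, harmonized: bool) -> set[str]:
    if kind == "gene":
        if harmonized:
            return {assoc.gene.symbol} if assoc.gene.symbol else set()
        return {extract_fields(assoc.raw).gene.strip()} - {""}
    if kind == "variant":
        if harmonized:
            keys = set()
            for v in assoc.variants:
                keys.add(v.allele_key or f"{assoc.gene.symbol}::{v.name.strip().lower()}")
            return keys
        ex = extract_fields(assoc.raw)
        return {f"{ex.gene.strip()}::{ex.variant_name.strip()}"}
    if kind == "disease":
        if harmonized:
            return {assoc.disease.doid} if assoc.disease.doid else set()
        return {extract_fields(assoc.raw).disease.strip()} - {""}
    if kind == "drug":
        if assoc.source not in SOURCES_WITH_DRUGS:
            return set()
        if harmonized:
            if assoc.drugs is None:
                return set()
            return {c.normalized_id or c.input_name.strip().lower()
                    for c in assoc.drugs.components}
        return set(extract_fields(assoc.raw).drugs or []) - {""}
    if kind == "publication":
        if harmonized:
            return set(assoc.evidence.documents)
        return set(extract_fields(assoc.raw).documents) - {""}
    if kind == "evidence_code":
        if harmonized:
            return {assoc.evidence.harmonized_level.value}
        return {assoc.evidence.source_level.strip()} - {""}
    raise ValueError(f"unknown element kind {kind!r}")


def element_sets(store: Iterable[Association], kind: str,
                 harmonized: bool = True) -> ElementSets:
    """Collect the unique element keys of each source, harmonized or raw."""
    sets: dict[str, set[str]] = {}
    for assoc in store:
        sets.setdefault(assoc.source.value, set()).update(
            _element_keys(assoc, kind, harmonized))
    return ElementSets(kind, sets)


@dataclass
class OverlapResult:
    union_size: int
    multiplicity: dict[int, int]  # elements seen in exactly k sources
    overlap_percent: float  # share of union seen in >= 2 sources


def overlap_fraction(sets: ElementSets) -> OverlapResult:
    """Overlap of unique elements across sources.

    Overlap percent is defined as the share of union elements present in at
    least two sources; the multiplicity histogram sums to the union size.
    """
    if len(sets.sets) < 2:
        raise ValueError("overlap requires elements from at least 2 sources")
    counts = Counter()
    for keys in sets.sets.values():
        counts.update(keys)
    if not counts:
        raise ValueError("empty element union")
    multiplicity = Counter(counts.values())
    union = sum(multiplicity.values())
    shared = sum(n for k, n in multiplicity.items() if k >= 2)
    return OverlapResult(union, dict(sorted(multiplicity.items())),
                         100.0 * shared / union)


def upset_attribution(membership: dict[str, set[str]]) -> dict[str, tuple[str, ...]]:
    """Attribute each element to the full combination of sources containing it.

    Combination counts therefore partition the element universe (UpSet-style
    attribution to the largest containing set).
    """
    out = {}
    for element, sources in membership.items():
        if not sources:
            raise ValueError(f"element {element!r} has empty membership")
        out[element] = tuple(sorted(sources))
    return out


def membership_from_sets(sets: ElementSets) -> dict[str, set[str]]:
    membership: dict[str, set[str]] = {}
    for source, keys in sets.sets.items():
        for key in keys:
            membership.setdefault(key, set()).add(source)
    return membership


# ---------------------------------------------------------------------------
# Fisher exact odds ratios


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_or(t: ContingencyTable2x2) -> tuple[float, float]:
    """Sample odds ratio (a*d)/(b*c) and two-sided Fisher exact p.

    The p-value sums hypergeometric probabilities no larger than that of the
    observed table. With b*c = 0 the odds ratio is reported as infinity; the
    p-value is still defined.
    """
    _, p = scipy_stats.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                    alternative="two-sided")
    if t.b * t.c == 0:
        return math.inf, float(p)
    return (t.a * t.d) / (t.b * t.c), float(p)


# ---------------------------------------------------------------------------
# Store-level summaries


def disease_group_proportions(store: list[Association],
                              threshold: float = 0.05
                              ) -> dict[str, tuple[float, bool]]:
    """Fraction of associations per TopNode disease group.

    Associations without a group assignment are pooled as "other". Each group
    carries a flag marking whether it reaches the reporting threshold
    (default 5% of the dataset). Fractions sum to 1.
    """
    if not store:
        raise ValueError("empty store")
    counts = Counter(a.disease.topnode or "other" for a in store)
    total = sum(counts.values())
    return {group: (n / total, n / total >= threshold)
            for group, n in sorted(counts.items(), key=lambda kv: -kv[1])}


@dataclass
class PublicationSummary:
    n_interpretations: int
    n_unique_documents: int
    ratio: float
    shared_documents: dict[str, int]  # document -> number of sources citing it


def interpretations_per_publication(store: list[Association]) -> PublicationSummary:
    """Interpretations per unique cited document, over the whole store."""
    docs_by_source: dict[str, set[str]] = {}
    all_docs: set[str] = set()
    for assoc in store:
        docs = set(assoc.evidence.documents)
        all_docs |= docs
        docs_by_source.setdefault(assoc.source.value, set()).update(docs)
    if not all_docs:
        raise ValueError("store cites no documents")
    source_count = Counter()
    for docs in docs_by_source.values():
        source_count.update(docs)
    shared = {doc: n for doc, n in sorted(source_count.items()) if n >= 2}
    return PublicationSummary(
        n_interpretations=len(store),
        n_unique_documents=len(all_docs),
        ratio=len(store) / len(all_docs),
        shared_documents=shared,
    )
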