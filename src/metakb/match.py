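"""Graded matching of patient variants and diseases against the store.

Variant hits are classified by intersection semantics, most specific first:

* ``exact`` — complete reciprocal intersection and equal alternate alleles;
* ``positional`` — complete reciprocal intersection, alleles differ/absent;
* ``focal`` — partial intersection, but both overlap fractions
  (|∩|/|query| and |∩|/|target|) strictly exceed 0.10;
* ``regional`` — any other nonzero intersection;
* ``gene_level`` — matched by gene symbol only.

Disease constraints use ontology lineage: terms match only when identical or
ancestor/descendant, with distance counted in TopNode boundary crossings, so
"grouped" matching (distance 0) means both terms sit in one TopNode subtree
on one lineage. Evidence-tier filtering is only meaningful for exact variant
matches — broader matches would need contextual re-grading of the evidence —
so requesting it with any other mode is refused.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .adapters import CohortSample, CohortVariant
from .diseases import OntologyGraph, disease_distance
from .model import (Association, EvidenceLevel, GenomicInterval, MatchClass,
                    Tier, VariantNorm)


class StrategyError(ValueError):
    """Search strategy violates a combination rule."""


class DiseaseMode(str, enum.Enum):
    SINGULAR = "singular"  # identical ontology terms
    GROUPED = "grouped"    # lineage match within one TopNode subtree
    ANY = "any"            # no disease constraint


_VARIANT_MODES = (MatchClass.EXACT, MatchClass.POSITIONAL, MatchClass.FOCAL,
                  MatchClass.REGIONAL, MatchClass.GENE_LEVEL)


@dataclass(frozen=True)
class SearchStrategy:
    variant_mode: MatchClass = MatchClass.EXACT
    disease_mode: DiseaseMode = DiseaseMode.ANY
    tier_filter: Optional[Tier] = None  # only Tier.I is meaningful

    def validate(self) -> None:
        if self.variant_mode not in _VARIANT_MODES:
            raise StrategyError(f"invalid variant mode {self.variant_mode}")
        if self.tier_filter is not None and self.variant_mode is not MatchClass.EXACT:
            raise StrategyError(
                "evidence tier filtering can only be used with an exact "
                "search strategy")


@dataclass(frozen=True)
class MatchResult:
    association: Association
    match_class: MatchClass
    disease_distance: Optional[int]
    level: EvidenceLevel
    tier: Tier


@dataclass(frozen=True)
class PatientMatchSummary:
    sample_id: str
    best_level: Optional[EvidenceLevel]
    n_matches: int
    strategy: SearchStrategy


# ---------------------------------------------------------------------------
# Interval classification


def _effective(iv: GenomicInterval) -> tuple[int, int]:
    """Zero-length (insertion-point) intervals occupy the following base."""
    return (iv.start, iv.end) if iv.end > iv.start else (iv.start, iv.start + 1)


def classify_variant_match(query: GenomicInterval,
                           target: VariantNorm | GenomicInterval) -> MatchClass:
    """Classify one query interval against one target variant."""
    if query.end <= query.start:
        raise ValueError("zero-length query interval")
    tiv = target.interval if isinstance(target, VariantNorm) else target
    if tiv is None:
        return MatchClass.NONE
    if query.chromosome != tiv.chromosome or query.assembly != tiv.assembly:
        return MatchClass.NONE
    ts, te = _effective(tiv)
    inter = min(query.end, te) - max(query.start, ts)
    if inter <= 0:
        return MatchClass.NONE
    if inter == (query.end - query.start) and inter == (te - ts):
        q_alt = query.alt_allele.upper()
        t_alt = tiv.alt_allele.upper()
        if q_alt and q_alt == t_alt:
            return MatchClass.EXACT
        return MatchClass.POSITIONAL
    if (inter / (query.end - query.start) > 0.10
            and inter / (te - ts) > 0.10):
        return MatchClass.FOCAL
    return MatchClass.REGIONAL


def _best_variant_class(query: GenomicInterval, assoc: Association) -> MatchClass:
    best = MatchClass.NONE
    for variant in assoc.variants:
        if variant.interval is None:
            continue
        cls = classify_variant_match(query, variant)
        if cls.rank < best.rank:
            best = cls
    return best


# ---------------------------------------------------------------------------
# Search


@dataclass(frozen=True)
class QueryVariant:
    interval: GenomicInterval
    gene: Optional[str] = None

    @property
    def search_interval(self) -> GenomicInterval:
        s, e = _effective(self.interval)
        iv = self.interval
        if (s, e) == (iv.start, iv.end):
            return iv
        return GenomicInterval(iv.assembly, iv.chromosome, s, e,
                               iv.ref_allele, iv.alt_allele)


def _disease_ok(strategy: SearchStrategy, query_doid: Optional[str],
                assoc: Association, graph: Optional[OntologyGraph]
                ) -> tuple[bool, Optional[int]]:
    if strategy.disease_mode is DiseaseMode.ANY:
        return True, None
    target = assoc.disease.doid
    if query_doid is None or target is None:
        return False, None
    if strategy.disease_mode is DiseaseMode.SINGULAR:
        return query_doid == target, 0 if query_doid == target else None
    if graph is None:
        raise StrategyError("grouped disease matching requires an ontology graph")
    if query_doid not in graph.graph or target not in graph.graph:
        return False, None
    dist = disease_distance(query_doid, target, graph)
    return dist == 0, dist


def search(query: QueryVariant, query_doid: Optional[str],
           store: Iterable[Association], strategy: SearchStrategy,
           graph: Optional[OntologyGraph] = None) -> list[MatchResult]:
    """Search the harmonized store for one query variant (+ disease).

    Results keep hits whose match class is at least as specific as the
    strategy's variant mode, deduplicated by (source, record id), sorted by
    (evidence level, match specificity).
    """
    strategy.validate()
    qiv = query.search_interval
    best: dict[tuple[str, str], MatchResult] = {}
    for assoc in store:
        cls = _best_variant_class(qiv, assoc)
        if (strategy.variant_mode is MatchClass.GENE_LEVEL
                and cls is MatchClass.NONE and query.gene
                and assoc.gene.symbol == query.gene):
            cls = MatchClass.GENE_LEVEL
        if cls is MatchClass.NONE or cls.rank > strategy.variant_mode.rank:
            continue
        ok, dist = _disease_ok(strategy, query_doid, assoc, graph)
        if not ok:
            continue
        if (strategy.tier_filter is not None
                and assoc.evidence.tier is not strategy.tier_filter):
            continue
        result = MatchResult(assoc, cls, dist, assoc.evidence.harmonized_level,
                             assoc.evidence.tier)
        key = (assoc.source.value, assoc.record_id)
        prev = best.get(key)
        if prev is None or (result.level.rank, result.match_class.rank) < (
                prev.level.rank, prev.match_class.rank):
            best[key] = result
    return sorted(best.values(),
                  key=lambda r: (r.level.rank, r.match_class.rank,
                                 r.association.source.value,
                                 r.association.record_id))


def match_patient(variants: list[CohortVariant], sample: CohortSample,
                  store: Iterable[Association], strategy: SearchStrategy,
                  graph: Optional[OntologyGraph] = None) -> PatientMatchSummary:
    """Union of search results over one sample's (consequence-filtered)
    variants. Samples with no variants yield n_matches=0 but remain valid
    members of cohort denominators."""
    store = list(store)
    merged: dict[tuple[str, str], MatchResult] = {}
    for variant in variants:
        query = QueryVariant(variant.interval, gene=variant.gene_symbol)
        for result in search(query, sample.doid, store, strategy, graph):
            key = (result.association.source.value, result.association.record_id)
            prev = merged.get(key)
            if prev is None or result.level.rank < prev.level.rank:
                merged[key] = result
    best_level = None
    if merged:
        best_level = min((r.level for r in merged.values()),
                         key=lambda lv: lv.rank)
    return PatientMatchSummary(sample.sample_id, best_level, len(merged), strategy)


def match_gene_level(variants: list[CohortVariant],
                     store: Iterable[Association]) -> list[Association]:
    """Associations whose (normalized) gene symbol equals any variant's gene.

    No evidence level adjustment is performed for this deliberately
    imprecise aggregation strategy.
    """
    genes = {v.gene_symbol for v in variants}
    return [a for a in store if a.gene.symbol and a.gene.symbol in genes]


# ---------------------------------------------------------------------------
# Cohort coverage


@dataclass
class Cohort:
    samples: list[CohortSample]
    variants_by_sample: dict[str, list[CohortVariant]] = field(default_factory=dict)

    def variants_of(self, sample_id: str) -> list[CohortVariant]:
        return self.variants_by_sample.get(sample_id, [])


@dataclass(frozen=True)
class _Hit:
    assoc_index: int
    match_rank: int  # most specific interval class over the sample's variants
    gene_only: bool


def _index_store(store: list[Association]):
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    by_gene: dict[str, list[int]] = defaultdict(list)
    for i, assoc in enumerate(store):
        if assoc.gene.symbol:
            by_gene[assoc.gene.symbol].append(i)
        for variant in assoc.variants:
            iv = variant.interval
            if iv is None:
                continue
            s, e = _effective(iv)
            trees[(iv.assembly, iv.chromosome)].addi(s, e, (i, variant))
    return trees, by_gene


def _sample_hits(variants, trees, by_gene) -> dict[int, _Hit]:
    hits: dict[int, _Hit] = {}
    gene_idx: set[int] = set()
    for v in variants:
        gene_idx.update(by_gene.get(v.gene_symbol, ()))
        qiv = QueryVariant(v.interval).search_interval
        tree = trees.get((qiv.assembly, qiv.chromosome))
        if tree is None:
            continue
        for node in tree.overlap(qiv.start, qiv.end):
            i, variant = node.data
            cls = classify_variant_match(qiv, variant)
            if cls is MatchClass.NONE:
                continue
            prev = hits.get(i)
            if prev is None or cls.rank < prev.match_rank:
                hits[i] = _Hit(i, cls.rank, gene_only=False)
    for i in gene_idx:
        if i not in hits:
            hits[i] = _Hit(i, MatchClass.GENE_LEVEL.rank, gene_only=True)
    return hits


def cohort_coverage(cohort: Cohort, store: list[Association],
                    strategies: list[SearchStrategy],
                    graph: Optional[OntologyGraph] = None,
                    per_source: bool = True) -> dict:
    """Fraction of samples with >= 1 matching interpretation, per strategy.

    Denominators always include samples with zero qualifying variants.
    Coverage is reported for the aggregate store and, optionally, each
    single-source subset. Returns {strategy index: {"aggregate": f,
    source: f, ...}}.
    """
    if not cohort.samples:
        raise ValueError("empty cohort")
    for strategy in strategies:
        strategy.validate()
    store = list(store)
    trees, by_gene = _index_store(store)
    dist_cache: dict[tuple[str, str], Optional[int]] = {}

    def grouped_dist(q: Optional[str], t: Optional[str]) -> Optional[int]:
        if q is None or t is None or graph is None:
            return None
        if q not in graph.graph or t not in graph.graph:
            return None
        key = (q, t)
        if key not in dist_cache:
            dist_cache[key] = disease_distance(q, t, graph)
        return dist_cache[key]

    coverage: dict[int, dict[str, float]] = {}
    subsets = ["aggregate"]
    if per_source:
        subsets += sorted({a.source.value for a in store})
    counts = {si: {sub: 0 for sub in subsets} for si in range(len(strategies))}

    for sample in cohort.samples:
        hits = _sample_hits(cohort.variants_of(sample.sample_id), trees, by_gene)
        for si, strategy in enumerate(strategies):
            matched_sources: set[str] = set()
            matched = False
            for hit in hits.values():
                if hit.match_rank > strategy.variant_mode.rank:
                    continue
                assoc = store[hit.assoc_index]
                if strategy.disease_mode is DiseaseMode.SINGULAR:
                    if sample.doid is None or sample.doid != assoc.disease.doid:
                        continue
                elif strategy.disease_mode is DiseaseMode.GROUPED:
                    if grouped_dist(sample.doid, assoc.disease.doid) != 0:
                        continue
                if (strategy.tier_filter is not None
                        and assoc.evidence.tier is not strategy.tier_filter):
                    continue
                matched = True
                matched_sources.add(assoc.source.value)
            if matched:
                counts[si]["aggregate"] += 1
            for src in matched_sources:
                if src in counts[si]:
                    counts[si][src] += 1
    n = len(cohort.samples)
    for si in range(len(strategies)):
        coverage[si] = {sub: counts[si][sub] / n for sub in subsets}
    return coverage
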