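"""Gene symbol normalization against an approved-symbol/alias table.

The table follows the HGNC ``non_alt_loci_set`` JSON layout: each document
carries an approved ``symbol`` plus ``alias_symbol`` and ``prev_symbol``
lists. Retired and alternate symbols form a secondary alias table; an alias
shared by two genes is ambiguous and yields no normalized symbol, mirroring
standard curation practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model import GeneNorm, GeneStatus


@dataclass
class GeneTable:
    """Primary approved symbols plus an alias -> {primary symbols} map."""

    primary_symbols: set[str]
    alias_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        # an approved symbol is never its own alias
        for sym in self.primary_symbols:
            self.alias_map.pop(sym, None)

    @classmethod
    def from_hgnc_json(cls, path) -> "GeneTable":
        """Load from an HGNC-style JSON file (``response.docs`` layout)."""
        with open(path) as fh:
            data = json.load(fh)
        docs = data["response"]["docs"] if "response" in data else data
        primary = set()
        alias_map: dict[str, set[str]] = {}
        for doc in docs:
            sym = doc["symbol"].upper()
            primary.add(sym)
            for alias in list(doc.get("alias_symbol", [])) + list(doc.get("prev_symbol", [])):
                alias_map.setdefault(alias.upper(), set()).add(sym)
        return cls(primary, alias_map)


def normalize_gene(symbol: str, table: GeneTable) -> GeneNorm:
    """Resolve a gene symbol: primary lookup first, aliases second.

    Symbols are matched case-sensitively after uppercasing (HGNC symbols are
    uppercase). An empty input, an alias shared between genes, or a miss in
    both tables yields a failure status with an empty symbol.
    """
    query = (symbol or "").strip().upper()
    if not query:
        return GeneNorm(status=GeneStatus.UNMATCHED)
    if query in table.primary_symbols:
        return GeneNorm(symbol=query, matched_via="primary", status=GeneStatus.NORMALIZED)
    hits = table.alias_map.get(query, set())
    if len(hits) == 1:
        return GeneNorm(symbol=next(iter(hits)), matched_via="alias",
                        status=GeneStatus.NORMALIZED)
    if len(hits) > 1:
        return GeneNorm(status=GeneStatus.AMBIGUOUS_ALIAS)
    return GeneNorm(status=GeneStatus.UNMATCHED)
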