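"""Drug name normalization through an ordered chain of synonym tables.

Emulates the cascaded lookup used for therapy harmonization: each name is
queried against synonym tables in priority order and the first table that
resolves wins. Combination therapy strings are split into components before
lookup; unresolved components are kept with an absent identifier rather than
dropped, so no therapy silently disappears.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass

from .model import DrugComponent, DrugNorm

#: Delimiters that denote combination therapies; " or " separates listed
#: alternatives within one interpretation and is split the same way.
_SPLIT_RE = re.compile(r"\s+and\s+|\s+\+\s+|,|\s+or\s+")
_PAREN_TAG_RE = re.compile(r"\s*\((?:combination|monotherapy)\)\s*$", re.IGNORECASE)


@dataclass
class DrugSynonymChain:
    """Ordered synonym tables: name (lower-cased) -> (identifier, label)."""

    tables: list[dict[str, tuple[str, str]]]

    @classmethod
    def from_tsv_paths(cls, paths) -> "DrugSynonymChain":
        tables = []
        for path in paths:
            table: dict[str, tuple[str, str]] = {}
            with open(path, newline="") as fh:
                for row in csv.DictReader(
                        (l for l in fh if not l.startswith("#")), delimiter="\t"):
                    table[row["name"].strip().lower()] = (
                        row["id"].strip(), row["label"].strip())
            tables.append(table)
        return cls(tables)

    def resolve(self, name: str) -> tuple[str, str] | None:
        key = name.strip().lower()
        for table in self.tables:
            if key in table:
                return table[key]
        return None


def split_combination(text: str) -> list[str]:
    """Split a therapy string into component names, stripping tags like
    "(combination)"."""
    cleaned = _PAREN_TAG_RE.sub("", (text or "").strip())
    parts = [p.strip() for p in _SPLIT_RE.split(cleaned)]
    return [p for p in parts if p]


def normalize_drug(name: str, chain: DrugSynonymChain) -> DrugNorm:
    """Normalize one therapy string (possibly a combination).

    Each component resolves independently through the chain in priority
    order, case-insensitively; the first table with the name wins.
    """
    parts = split_combination(name)
    if not parts:
        parts = [(name or "").strip()]
    components = []
    for part in parts:
        hit = chain.resolve(part)
        if hit:
            components.append(DrugComponent(part, hit[0], hit[1]))
        else:
            components.append(DrugComponent(part))
    return DrugNorm(tuple(components), is_combination=len(components) > 1)


def normalize_drug_list(names, chain: DrugSynonymChain) -> DrugNorm:
    """Normalize several therapy names into one (possibly combination) entry."""
    components: list[DrugComponent] = []
    for name in names:
        components.extend(normalize_drug(name, chain).components)
    return DrugNorm(tuple(components), is_combination=len(components) > 1)
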