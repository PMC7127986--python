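"""Evidence level harmonization to the AMP/ASCO/CAP four-level scheme.

Each knowledgebase grades evidence with its own vocabulary ("Level 3A",
"Preclinical", "Clinical practice", "Tier 2", ...). The shipped mapping
table assigns every source code to one of the harmonized levels A-D, where
A and B constitute tier I (guideline/trial-backed) and C and D tier II
(case studies / preclinical). The mapping is total over the shipped table;
an unknown (source, code) pair is a hard error, never a silent default.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass

from .model import EvidenceLevel, Source, Tier


class EvidenceMappingError(KeyError):
    """(source, code) pair not present in the evidence map."""


_DASHES = str.maketrans({"–": "-", "—": "-"})


def _norm_code(code: str) -> str:
    return re.sub(r"\s+", " ", code.translate(_DASHES).strip().lower())


@dataclass
class EvidenceMap:
    """(source, normalized code) -> harmonized level; tier follows the level."""

    cells: dict[tuple[Source, str], EvidenceLevel]

    @classmethod
    def from_tsv(cls, path) -> "EvidenceMap":
        cells: dict[tuple[Source, str], EvidenceLevel] = {}
        with open(path, newline="") as fh:
            rows = csv.DictReader((l for l in fh if not l.startswith("#")),
                                  delimiter="\t")
            for row in rows:
                source = Source.coerce(row["source"].strip())
                cells[(source, _norm_code(row["code"]))] = EvidenceLevel(
                    row["level"].strip())
        return cls(cells)

    def sources(self) -> set[Source]:
        return {s for s, _ in self.cells}


def map_evidence(
    source: Source | str, source_code: str, emap: EvidenceMap
) -> tuple[EvidenceLevel, Tier]:
    """Resolve a source evidence code to (harmonized level, tier).

    Lookup is by exact cell, case-insensitively with whitespace and dash
    variants collapsed. Composite codes as printed in the mapping table
    ("Level 1/2A /R1", "Phase 0, preclinical") match on any listed member;
    members that resolve must agree on the level.
    """
    src = Source.coerce(source)
    code = _norm_code(source_code)
    hit = emap.cells.get((src, code))
    if hit is not None:
        return hit, hit.tier
    members = [m.strip() for m in re.split(r"[/,]", code) if m.strip()]
    if len(members) > 1:
        levels = {emap.cells[(src, m)]
                  for m in members if (src, m) in emap.cells}
        if len(levels) == 1:
            level = next(iter(levels))
            return level, level.tier
    raise EvidenceMappingError(
        f"no evidence mapping for source={src.value} code={source_code!r}")
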