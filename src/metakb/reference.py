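"""Synthetic reference sequence model.

Allele keying needs flanking reference sequence around each variant locus.
Rather than shipping genome FASTA, this module defines a deterministic
synthetic reference: the base at every position is a fixed hash of
(assembly, chromosome, position), overridden by the reference alleles
planted in the bundled coordinate lookup so that lookup rows always agree
with the reference they are keyed against. It is a synthetic stand-in with
the same interface a real reference reader would have, not genome sequence.
"""

from __future__ import annotations

import zlib
from functools import lru_cache

from .resources import load_coordinate_lookup
from .variants import ReferenceSlice

_BASES = "ACGT"


@lru_cache(maxsize=1)
def _planted() -> dict[tuple[str, str, int], str]:
    """(assembly, chromosome, 0-based pos) -> base, from lookup-table refs."""
    planted: dict[tuple[str, str, int], str] = {}
    for interval in load_coordinate_lookup().values():
        for i, base in enumerate(interval.ref_allele):
            planted[(interval.assembly, interval.chromosome,
                     interval.start + i)] = base
    return planted


def base_at(assembly: str, chromosome: str, pos: int) -> str:
    """Deterministic synthetic base at a 0-based position."""
    override = _planted().get((assembly, chromosome, pos))
    if override:
        return override
    h = zlib.crc32(f"{assembly}:{chromosome}:{pos}".encode())
    return _BASES[h & 3]


def get_slice(assembly: str, chromosome: str, start: int, end: int) -> ReferenceSlice:
    """Reference slice covering [start, end), 0-based half-open."""
    seq = "".join(base_at(assembly, chromosome, p) for p in range(start, end))
    return ReferenceSlice(assembly, chromosome, start, seq)


def slice_around(interval, flank: int = 30) -> ReferenceSlice:
    """Slice covering an interval's locus plus symmetric flanks."""
    start = max(0, interval.start - flank)
    return get_slice(interval.assembly, interval.chromosome,
                     start, interval.end + flank)
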