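"""Variant harmonization: coordinates, genomic HGVS, allele keys, protein edits.

Somatic knowledgebases describe the same genomic change in many spellings:
explicit coordinates, free-text labels ("V600E", "amplification"), and
protein-level HGVS in several non-canonical insertion syntaxes. This module
resolves all of them to comparable canonical forms:

* :func:`infer_coordinates` — explicit coordinates pass through; otherwise a
  (gene, label) lookup table resolves known labels; otherwise rule-based
  handling maps coordinate-free categorical labels (amplification,
  overexpression, oncogenic mutation, ...) onto the gene's full locus.
* :func:`assemble_hgvs_g` — build a genomic HGVS string from an interval;
  :func:`parse_hgvs_g` is the strict grammar it must satisfy.
* :func:`canonical_allele_key` — a deterministic, registry-style identifier:
  the edit is applied to a reference slice and reduced to its maximally
  prefix-then-suffix-trimmed (hence 3'-most, right-shifted) form, so any two
  HGVS spellings of the same resulting sequence collapse to one key.
* :func:`normalize_protein_change` — apply a protein edit to a sequence
  window, re-derive the minimal 3'-shifted description, and rewrite
  insertions of the immediately preceding run as duplications (the HGVS
  ``dup`` rule). This is what makes p.E770delinsEAYVM, p.M774insAYVM and
  p.A775_G776insYVMA collapse to the single form p.Y772_A775dup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .genes import GeneNorm
from .model import GenomicInterval, GeneStatus, VariantCategory


class HgvsSyntaxError(ValueError):
    """String does not parse under the strict genomic-HGVS grammar."""


class AccessionLookupError(KeyError):
    """(assembly, chromosome) missing from the accession table."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele/residues contradict the reference sequence."""


# ---------------------------------------------------------------------------
# Coordinate inference

#: Coordinate-free labels transformed onto full gene coordinates. Matching is
#: case-insensitive after collapsing separators and trailing plural "s".
CATEGORICAL_LOCUS_LABELS = frozenset({
    "amplification",
    "deletion",
    "overexpression",
    "loss-of-function mutation",
    "gain-of-function mutation",
    "oncogenic mutation",
    "mutation",
})


def _norm_label(label: str) -> str:
    s = re.sub(r"[\s_]+", " ", (label or "").strip().lower())
    s = s.replace("loss of function", "loss-of-function")
    s = s.replace("gain of function", "gain-of-function")
    if s.endswith("s") and s[:-1] in CATEGORICAL_LOCUS_LABELS:
        s = s[:-1]
    return s


@dataclass(frozen=True)
class CoordinateInference:
    interval: Optional[GenomicInterval]
    category: VariantCategory
    flagged: bool = False  # no gene and no explicit coordinates


def infer_coordinates(
    variant_name: str,
    gene: GeneNorm,
    lookup: dict[tuple[str, str], GenomicInterval],
    gene_loci: dict[str, GenomicInterval],
    explicit: Optional[GenomicInterval] = None,
) -> CoordinateInference:
    """Resolve a variant label to a genomic interval.

    ``lookup`` is keyed by (gene symbol, lower-cased label) — the local
    stand-in for a name->coordinate catalog. ``gene_loci`` maps gene symbols
    to their full locus. Explicit coordinates always pass through untouched.
    """
    if explicit is not None:
        return CoordinateInference(explicit, VariantCategory.ALLELE_SPECIFIC)
    if gene.status is not GeneStatus.NORMALIZED:
        return CoordinateInference(None, VariantCategory.UNRESOLVED, flagged=True)
    # sources decorate labels ("BRAF:V600E", "BRAF V600E", "p.V600E"); try the
    # undecorated spellings too
    base = (variant_name or "").strip().lower()
    candidates = [base]
    g = gene.symbol.lower()
    for prefix in (f"{g}:", f"{g} ", f"{g}-", "p."):
        if base.startswith(prefix):
            candidates.append(base[len(prefix):].strip())
    for cand in candidates:
        hit = lookup.get((gene.symbol, cand))
        if hit is not None:
            category = (VariantCategory.ALLELE_SPECIFIC if hit.alt_allele
                        else VariantCategory.CATEGORICAL)
            return CoordinateInference(hit, category)
    if _norm_label(variant_name) in CATEGORICAL_LOCUS_LABELS:
        locus = gene_loci.get(gene.symbol)
        if locus is not None:
            return CoordinateInference(locus, VariantCategory.CATEGORICAL)
    return CoordinateInference(None, VariantCategory.UNRESOLVED)


# ---------------------------------------------------------------------------
# Genomic HGVS grammar

_ACC = r"(?P<acc>[A-Z]{2}_\d+\.\d+)"
_HGVS_PATTERNS = {
    "sub": re.compile(_ACC + r":g\.(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$"),
    "del": re.compile(_ACC + r":g\.(?P<start>\d+)(?:_(?P<end>\d+))?del$"),
    "ins": re.compile(_ACC + r":g\.(?P<left>\d+)_(?P<right>\d+)ins(?P<alt>[ACGT]+)$"),
    "delins": re.compile(
        _ACC + r":g\.(?P<start>\d+)(?:_(?P<end>\d+))?delins(?P<alt>[ACGT]+)$"),
    "dup": re.compile(_ACC + r":g\.(?P<start>\d+)(?:_(?P<end>\d+))?dup$"),
}


@dataclass(frozen=True)
class HgvsGenomic:
    """Parsed genomic HGVS: accession plus a 0-based half-open edit.

    ``ref`` is the stated reference allele when the syntax carries one
    (substitutions only); ``alt`` is None for dup (materialized only against
    a reference sequence).
    """

    accession: str
    kind: str  # sub | del | ins | delins | dup
    start: int  # 0-based
    end: int    # half-open
    ref: Optional[str]
    alt: Optional[str]


def parse_hgvs_g(hgvs: str) -> HgvsGenomic:
    """Parse under the strict genomic grammar; raise HgvsSyntaxError else."""
    for kind, pat in _HGVS_PATTERNS.items():
        m = pat.match(hgvs)
        if not m:
            continue
        g = m.groupdict()
        if kind == "sub":
            pos = int(g["pos"])
            return HgvsGenomic(g["acc"], kind, pos - 1, pos, g["ref"], g["alt"])
        if kind == "ins":
            left, right = int(g["left"]), int(g["right"])
            if right != left + 1:
                raise HgvsSyntaxError(
                    f"insertion flanks must be adjacent: {hgvs!r}")
            return HgvsGenomic(g["acc"], kind, left, left, None, g["alt"])
        start = int(g["start"])
        end = int(g["end"]) if g.get("end") else start
        if end < start:
            raise HgvsSyntaxError(f"end < start in {hgvs!r}")
        alt = g.get("alt") if kind == "delins" else ("" if kind == "del" else None)
        return HgvsGenomic(g["acc"], kind, start - 1, end, None, alt)
    raise HgvsSyntaxError(f"not a recognized genomic HGVS string: {hgvs!r}")


def assemble_hgvs_g(
    interval: GenomicInterval, accession_table: dict[tuple[str, str], str]
) -> str:
    """Build a genomic HGVS string from an allele-specific interval.

    ``accession_table`` maps (assembly, chromosome) to a RefSeq accession.
    Positions in the output are 1-based per HGVS convention.
    """
    key = (interval.assembly, interval.chromosome)
    try:
        acc = accession_table[key]
    except KeyError:
        raise AccessionLookupError(
            f"no accession for assembly={key[0]} chromosome={key[1]}") from None
    ref, alt = interval.ref_allele.upper(), interval.alt_allele.upper()
    s0, e0 = interval.start, interval.end
    if len(ref) == 1 and len(alt) == 1 and e0 == s0 + 1:
        return f"{acc}:g.{s0 + 1}{ref}>{alt}"
    if alt == "" and e0 > s0:
        return f"{acc}:g.{s0 + 1}del" if e0 == s0 + 1 else f"{acc}:g.{s0 + 1}_{e0}del"
    if s0 == e0 and alt:
        return f"{acc}:g.{s0}_{s0 + 1}ins{alt}"
    if alt and e0 > s0:
        return (f"{acc}:g.{s0 + 1}delins{alt}" if e0 == s0 + 1
                else f"{acc}:g.{s0 + 1}_{e0}delins{alt}")
    raise ValueError(
        f"interval is not allele-specific: [{s0},{e0}) {ref!r}>{alt!r}")


# ---------------------------------------------------------------------------
# Canonical allele keys (registry stand-in)


@dataclass(frozen=True)
class ReferenceSlice:
    """A stretch of reference sequence: assembly, chromosome, 0-based offset."""

    assembly: str
    chromosome: str
    offset: int
    sequence: str

    def covers(self, start: int, end: int) -> bool:
        return self.offset <= start and end <= self.offset + len(self.sequence)

    def __getitem__(self, sl: slice) -> str:
        return self.sequence[sl.start - self.offset: sl.stop - self.offset]


def _trim(ref: str, alt: str) -> tuple[int, str, str]:
    """Maximal common-prefix then common-suffix trim; returns (prefix, ref', alt')."""
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    q = 0
    while q < len(ref) - p and q < len(alt) - p and ref[-1 - q] == alt[-1 - q]:
        q += 1
    return p, ref[p: len(ref) - q], alt[p: len(alt) - q]


def canonical_allele_key(hgvs_g: str, ref_slice: ReferenceSlice) -> str:
    """Deterministic canonical identifier for a genomic change.

    The edit is applied to the reference slice and the difference between the
    original and edited sequence is reduced by trimming the longest shared
    prefix and then the longest shared suffix; trimming the prefix first
    pushes repeats to the right, so the key is the fully right-shifted
    (3'-most) normalized representation, tagged by assembly. Two HGVS strings
    describing the same resulting sequence therefore yield equal keys.
    """
    parsed = parse_hgvs_g(hgvs_g)
    s, e = parsed.start, parsed.end
    if not ref_slice.covers(s, max(e, s)):
        raise ValueError(f"reference slice does not cover locus [{s},{e})")
    ref_here = ref_slice[s:e]
    if parsed.kind == "sub" and ref_here != parsed.ref:
        raise ReferenceMismatchError(
            f"{hgvs_g}: stated ref {parsed.ref!r} but reference has {ref_here!r}")
    alt = ref_here + ref_here if parsed.kind == "dup" else parsed.alt
    seq = ref_slice.sequence
    rel_s, rel_e = s - ref_slice.offset, e - ref_slice.offset
    edited = seq[:rel_s] + (alt or "") + seq[rel_e:]
    p, ref_min, alt_min = _trim(seq, edited)
    pos = ref_slice.offset + p
    return (f"{ref_slice.assembly}:{ref_slice.chromosome}:{pos}:"
            f"{ref_min}>{alt_min}")


# ---------------------------------------------------------------------------
# Protein-level normalization


class ProteinSyntaxError(ValueError):
    """Edit does not parse as a supported protein-level change."""


@dataclass(frozen=True)
class ProteinContext:
    """A protein sequence window with the residue number of its first position."""

    sequence: str
    start_residue: int

    def residue(self, number: int) -> str:
        i = number - self.start_residue
        if not (0 <= i < len(self.sequence)):
            raise ProteinSyntaxError(
                f"residue {number} outside window "
                f"{self.start_residue}-{self.start_residue + len(self.sequence) - 1}")
        return self.sequence[i]


_P_SUB = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_P_DELINS = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?delins([A-Z]+)$")
_P_INS = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?ins([A-Z]+)$")
_P_DUP = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?dup$")
_P_DEL = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?del$")


def _check_residue(ctx: ProteinContext, aa: str, number: int) -> None:
    found = ctx.residue(number)
    if found != aa:
        raise ReferenceMismatchError(
            f"stated residue {aa}{number} but window has {found}{number}")


def _apply_protein_edit(ctx: ProteinContext, edit: str) -> str:
    """Apply one protein edit to the window; returns the mutated window."""
    edit = edit.strip().removeprefix("p.")
    seq, s0 = ctx.sequence, ctx.start_residue

    m = _P_DELINS.match(edit)
    if m:
        a1, n1, a2, n2, ins = m.group(1), int(m.group(2)), m.group(3), m.group(4), m.group(5)
        n2 = int(n2) if n2 else n1
        _check_residue(ctx, a1, n1)
        if a2:
            _check_residue(ctx, a2, n2)
        i, j = n1 - s0, n2 - s0
        return seq[:i] + ins + seq[j + 1:]

    m = _P_INS.match(edit)
    if m:
        a1, n1, a2, n2, ins = m.group(1), int(m.group(2)), m.group(3), m.group(4), m.group(5)
        _check_residue(ctx, a1, n1)
        if a2:
            # standard syntax: insert between two adjacent residues
            n2 = int(n2)
            if n2 != n1 + 1:
                raise ProteinSyntaxError(
                    f"insertion flanks must be adjacent: {edit!r}")
            _check_residue(ctx, a2, n2)
        # literature shorthand X#insSEQ means "insert after residue X#"
        i = n1 - s0 + 1
        return seq[:i] + ins + seq[i:]

    m = _P_DUP.match(edit)
    if m:
        a1, n1, a2, n2 = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        n2 = int(n2) if n2 else n1
        _check_residue(ctx, a1, n1)
        if a2:
            _check_residue(ctx, a2, n2)
        i, j = n1 - s0, n2 - s0
        return seq[:j + 1] + seq[i:j + 1] + seq[j + 1:]

    m = _P_DEL.match(edit)
    if m:
        a1, n1, a2, n2 = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        n2 = int(n2) if n2 else n1
        _check_residue(ctx, a1, n1)
        if a2:
            _check_residue(ctx, a2, n2)
        return seq[: n1 - s0] + seq[n2 - s0 + 1:]

    m = _P_SUB.match(edit)
    if m:
        a1, n1, a2 = m.group(1), int(m.group(2)), m.group(3)
        _check_residue(ctx, a1, n1)
        i = n1 - s0
        return seq[:i] + a2 + seq[i + 1:]

    raise ProteinSyntaxError(f"unsupported protein edit syntax: {edit!r}")


def normalize_protein_change(ctx: ProteinContext, edit: str) -> str:
    """Canonicalize a protein-level change within a sequence window.

    The edit (any of substitution / del / ins / delins / dup syntax, including
    the single-anchor literature shorthand ``M774insAYVM``) is applied to the
    window; the minimal 3'-shifted description of the resulting change is then
    re-derived, and an insertion whose inserted run equals the immediately
    preceding residues is rewritten in ``dup`` form. Equivalent inputs map to
    the identical canonical edit; a no-op edit yields ``"="``.
    """
    mutated = _apply_protein_edit(ctx, edit)
    seq, s0 = ctx.sequence, ctx.start_residue
    p, ref_min, alt_min = _trim(seq, mutated)

    def label(i: int) -> str:
        return f"{seq[i]}{s0 + i}"

    if not ref_min and not alt_min:
        return "="
    if not ref_min:  # pure insertion after window index p-1
        run = alt_min
        if p >= len(run) and seq[p - len(run): p] == run:
            i, j = p - len(run), p - 1
            return f"{label(i)}dup" if i == j else f"{label(i)}_{label(j)}dup"
        if p == 0 or p >= len(seq):
            raise ProteinSyntaxError(
                "insertion at window boundary cannot be expressed; widen the window")
        return f"{label(p - 1)}_{label(p)}ins{run}"
    if not alt_min:  # pure deletion of window indices p .. p+len(ref_min)-1
        i, j = p, p + len(ref_min) - 1
        return f"{label(i)}del" if i == j else f"{label(i)}_{label(j)}del"
    if len(ref_min) == 1 and len(alt_min) == 1:
        return f"{label(p)}{alt_min}"
    i, j = p, p + len(ref_min) - 1
    if i == j:
        return f"{label(i)}delins{alt_min}"
    return f"{label(i)}_{label(j)}delins{alt_min}"
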