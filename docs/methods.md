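# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## The harmonized data model

An *association* is one curated assertion linking a variant (in a gene) and
a disease to a clinical implication, graded by evidence. Internally:

* **Coordinates** are 0-based half-open everywhere. Dialect readers convert
  on ingest (MAF and most knowledgebase payloads are 1-based inclusive;
  `"-"` alleles become empty strings; a MAF insertion becomes a zero-length
  interval at the insertion point) and writers convert back. This keeps
  interval arithmetic free of off-by-one cases; the round-trip is tested.
* **Verbatim payloads** are retained on every association. Harmonization is
  an annotation layer, never a rewrite; rejects (unmappable evidence codes,
  invariant violations, malformed records) are reported per source, never
  fatal.
* One association may carry **several variants**: a categorical concept
  ("oncogenic mutation") expands to the member alleles listed in an explicit
  per-source expansion table, while the categorical record itself is kept as
  the first entry. No expansion happens without a table entry.
* One source record with several therapy names becomes **one association**
  with a combination drug entry (`is_combination` iff more than one
  component), rather than several associations.

## Element normalization

**Genes.** Primary approved-symbol lookup, then a retired/alternate alias
table; an alias shared by two genes is ambiguous and yields no symbol.
Matching is case-sensitive after uppercasing, since approved symbols are
uppercase.

**Variants.** Explicit coordinates pass through untouched. Otherwise the
(gene, label) pair is looked up in a bundled name→coordinate catalog — the
offline stand-in for a somatic mutation catalog — after stripping common
label decorations (`GENE:`, `GENE `, `p.`). Otherwise rule-based handling
maps coordinate-free categorical labels (amplification, deletion,
overexpression, loss-/gain-of-function/oncogenic mutation) to the gene's
full locus. Remaining labels stay unresolved rather than guessed.

Allele-specific intervals are assembled into genomic HGVS (substitution,
del, ins, delins forms; a strict grammar ships with the package and every
assembled string must parse under it). The **allele key** is the offline
stand-in for registry identifiers: the edit is applied to a reference slice
and the original/edited pair is trimmed by longest common prefix first, then
longest common suffix. Prefix-first trimming pushes repeats rightward, so
the key is the fully 3'-shifted normalized representation, tagged by
assembly. Equal keys ⇔ equal resulting sequences over the slice; this is
property-tested against a sequence-application oracle over random repeat
contexts. An optional online resolver could replace keys with registry
identifiers; nothing in the package requires it.

Because no genome FASTA is shipped, reference sequence comes from a
deterministic synthetic model (`metakb.reference`): a fixed hash of
(assembly, chromosome, position), overridden by the reference alleles
planted in the coordinate catalog so catalog rows always verify. It is a
synthetic stand-in with a real reference reader's interface; substituting a
FASTA-backed implementation changes no other code.

**Protein changes.** The same 3'-shifting logic at residue level: apply the
edit (substitution, del, ins — including the single-anchor literature
shorthand `M774insAYVM` meaning "insert after M774" — delins, dup) to a
sequence window, re-derive the minimal shifted description, and rewrite an
insertion whose run equals the immediately preceding residues as `dup`.
Normalization is idempotent and preserves the mutated product
(property-tested). Insertions at the very edge of a window are refused
rather than mis-described: the window must contain flanking context.

**Diseases.** Case-insensitive exact label, then synonym, then per-source
shorthand table; ties are left unmapped with a review flag. Each mapped term
gets its nearest TopNode ancestor-or-self by minimal is-a path length (ties
break to the lexicographically smallest identifier); cancer-branch terms
with no TopNode ancestor fall back to the cancer root (DOID:162); terms
outside the cancer branch get no group. The bundled ontology is a
hand-built synthetic subset shaped like the cancer slim of a disease
ontology: ~29 nodes, 7 TopNode terms, including the ductal/lobular breast
carcinoma configuration needed to distinguish lineage matches from sibling
non-matches.

**Drugs.** An ordered chain of synonym tables (primary registry-style table,
then a secondary table carrying brand names and development codes); first
table that resolves wins, case-insensitively. Combination strings split on
`" and "`, `" + "`, `","` — and also `" or "`, since sources list therapy
alternatives that way — with parenthetical tags like `(combination)`
stripped. Unresolved components are kept with an absent identifier.

**Evidence.** A shipped total map from (source, code) to harmonized levels
A–D; A,B constitute tier I and C,D tier II, enforced as an invariant.
Composite codes ("Level 1/2A /R1", "Phase 0, preclinical") resolve on any
listed member, requiring member agreement. An unknown code is a hard
mapping error that sends the record to rejects. Evidence direction is
harmonized from free-text phrases via per-dialect prefix rules; unknown
phrases become `unstated`. A resistance finding still *supports* its
association (the direction concerns the evidence, not the therapeutic
sense).

**Documents.** `PMID: 123`, `pmid:123` and bare digits coalesce to
`PMID:123`; DOIs are lower-cased with a leading `doi:` stripped.

## Matching semantics

Match classes, most specific first: *exact* (complete reciprocal
intersection and equal alternate alleles — reference alleles are not
compared, since allele keying already guarantees locus identity),
*positional* (complete intersection, alleles differ or absent), *focal*
(both overlap fractions strictly > 0.10; the boundary value 0.10 itself is
regional), *regional* (any other nonzero intersection), *gene_level*
(symbol only, with no evidence-level adjustment). The classifier is verified
by exhaustive enumeration of all integer interval pairs in [0, 20) against
a brute-force set-intersection classifier. Zero-length query intervals are
an error at the classifier level; the search layer widens insertion-point
queries and targets to the following base.

Disease matching requires identity or an ancestor/descendant relationship;
distance counts TopNode slim members strictly between the endpoints,
minimized over paths where the DAG offers several. Any matching pair inside
one TopNode subtree scores 0; siblings never match. Nonzero distances
(lineages crossing TopNode boundaries) are defined and tested structurally,
but no external anchor exists for them beyond the 0 / no-match distinction.

Strategies combine a variant mode, a disease mode (singular / grouped /
any) and an optional tier-I filter. Tier filtering is refused with any
non-exact variant mode: broader matches would require contextual re-grading
of evidence assigned to a precise variant+disease context. Relaxing any
axis never shrinks the result set (tested). Results deduplicate by
(source, record id) and sort by (evidence level, match specificity).
Cohort coverage counts samples with ≥ 1 match; samples with zero qualifying
variants after the consequence filter stay in every denominator. The
consequence exclusion set is {Silent, 3'Flank, 3'UTR, 5'Flank, 5'UTR,
Intron, Splice_Region} (typographic primes normalized), i.e. only moderate-
and high-impact classes are matched.

## Consensus statistics

Overlap percent is defined as the share of union elements present in at
least two sources; the definition is applied identically to raw spellings
and harmonized keys, so the raw-vs-harmonized comparison isolates the
harmonization effect. UpSet attribution assigns each element to the full
combination of sources containing it (a partition of the element universe).
Fisher odds ratios are the sample cross-ratio (a·d)/(b·c) with the
two-sided exact p-value; the implementation is scipy's, cross-checked in
tests against a pure hypergeometric enumeration oracle on small tables.
The OR orientation follows the table as passed; nothing auto-inverts.

## The synthetic generator

The generator's defaults emulate the sharing structure seen across real
interpretation knowledgebases: per source, 30% of records are planted
*shared* interpretations — the same hotspot allele expressed in each
source's own spelling (label decorations, explicit left/right-equivalent
coordinates, ontology synonyms, brand vs generic drug names, one source
using retired gene symbols) — 15% are categorical concepts, and the rest
are unique to the source, drawn from per-source gene windows so most genes
stay unique. Cohorts default to 1,000 samples with a 12% zero-qualifying-
variant fraction and ~3 calls per sample, 45% of them at catalog hotspots.
All outputs are byte-deterministic in (config, seed). The ERBB2 exon-20
worked example (30 evidence rows spanning all six sources, shipped as a
bundled table) is embedded verbatim in the dumps by default.

What the generator does **not** emulate: real dump field inventories beyond
the element structure (the closed sources' payload schemas are not public),
transcript-level variant projection, multi-assembly records, curation noise
such as malformed or contradictory entries (tests construct those
explicitly), and cohort-scale disease frequency distributions. Passing
tests therefore demonstrate the correctness of the harmonization and
matching machinery under realistic structure, not the field-scale coverage
percentages a real cohort and full knowledgebase dumps would produce — at
this scale the coverage profile (e.g. ~66% variant-level, ~82% regional,
~29% disease-matched, ~13% tier I) mirrors the qualitative ordering, not
the exact magnitudes, of a production aggregation.

On the bundled worked-example table: direct enumeration of its printed
document identifiers yields 22 unique documents with one PMID (26598547)
cited by three sources; the table is shipped as printed and the accounting
is computed, not asserted.

## Numerical and policy choices

* Problem sizes: tests and the acceptance script use 40 records/source
  dumps and 1,000-sample cohorts — large enough for the binomial and
  monotonicity properties to be sharp, small enough to run in seconds.
* Tie-breaks: nearest-TopNode ties go to the lexicographically smallest
  identifier; search result dedup keeps the best (level, specificity) pair.
* Degenerate inputs: empty MAF/clinical files are valid (headers only);
  empty stores and single-source overlap are errors; unknown ontology terms
  raise rather than silently failing a match.
* The evidence map includes "Early trials" as a level-C spelling used by
  one source's exports alongside "Clinical trials I–II"; without it the
  bundled worked-example rows would reject.
* Exit codes in the CLI: 0 success, 2 config error, 3 format error,
  4 strategy-rule violation.

## Known limitations

* No cross-assembly liftover; GRCh37 and GRCh38 records coexist but never
  merge keys across assemblies.
* No transcript-aware projection of protein changes to genomic coordinates;
  a record needs explicit coordinates or a catalog hit.
* Oncogenicity calls, ranking models beyond (evidence level, match class),
  and any hosted/search-service layer are out of scope; the NDJSON store
  plus the query commands replace them.
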