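"""Quantify how much harmonization improves cross-source consensus.

Computes the overlap of unique interpretation elements across the six
sources twice — once on the verbatim (raw) spellings and once on the
harmonized keys — and runs the two-sided Fisher exact test used for group
comparisons.
"""

import tempfile

from metakb import (ContingencyTable2x2, element_sets, fisher_or,
                    harmonize_dumps, overlap_fraction)
from metakb.synthetic import FixtureConfig, generate_synthetic_kbs

with tempfile.TemporaryDirectory() as tmp:
    store = harmonize_dumps(generate_synthetic_kbs(
        FixtureConfig(seed=1), tmp)).associations

print("overlap across sources (share of union elements in >= 2 sources):")
for kind in ("gene", "variant", "disease", "drug", "publication"):
    raw = overlap_fraction(element_sets(store, kind, harmonized=False))
    har = overlap_fraction(element_sets(store, kind, harmonized=True))
    print(f"  {kind:12s} raw {raw.overlap_percent:5.1f}%  ->  "
          f"harmonized {har.overlap_percent:5.1f}%")
print("\nVariants, diseases and drugs gain from harmonization because the",
      "sources spell the same entity differently; genes barely move because",
      "approved symbols are already near-universal.")

oddsratio, p = fisher_or(ContingencyTable2x2(203, 4151, 97, 318))
print(f"\nFisher exact (publications vs genes in >= half the sources): "
      f"OR = {oddsratio:.3f}, P = {p:.2e}")
print("An OR far below 1 means genes are far more likely than publications",
      "to be curated by several knowledgebases.")
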