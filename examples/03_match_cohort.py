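"""Match a synthetic patient cohort against the harmonized store.

Builds a 1,000-sample cohort (MAF + clinical file), filters out low-impact
consequence classes, and reports the fraction of samples with at least one
interpretation at increasingly strict search stringencies. Samples with no
qualifying variants stay in every denominator.
"""

import tempfile
from pathlib import Path

from metakb import harmonize_dumps
from metakb.adapters import filter_by_consequence, read_clinical, read_maf
from metakb.match import Cohort, DiseaseMode, SearchStrategy, cohort_coverage
from metakb.model import MatchClass, Tier
from metakb.resources import load_oncotree_map, load_ontology
from metakb.synthetic import (CohortConfig, FixtureConfig,
                              generate_synthetic_cohort, generate_synthetic_kbs)

with tempfile.TemporaryDirectory() as tmp:
    store = harmonize_dumps(generate_synthetic_kbs(
        FixtureConfig(seed=1), Path(tmp) / "kbs")).associations
    maf, clin = generate_synthetic_cohort(
        CohortConfig(n_samples=1000, seed=2), Path(tmp) / "cohort")
    variants = read_maf(maf)
    samples = read_clinical(clin, load_oncotree_map())

retained, excluded = filter_by_consequence(variants)
print(f"{len(variants)} variant calls; {len(excluded)} excluded as "
      f"low-impact; {len(samples)} samples")
cohort = Cohort(samples)
for v in retained:
    cohort.variants_by_sample.setdefault(v.sample_id, []).append(v)
zero = sum(1 for s in samples if not cohort.variants_by_sample.get(s.sample_id))
print(f"{zero} samples ({100 * zero / len(samples):.1f}%) have no qualifying "
      "variants and stay in all denominators\n")

strategies = [
    ("variant (positional)", SearchStrategy(MatchClass.POSITIONAL)),
    ("any regional overlap", SearchStrategy(MatchClass.REGIONAL)),
    ("gene level", SearchStrategy(MatchClass.GENE_LEVEL)),
    ("variant + grouped disease",
     SearchStrategy(MatchClass.POSITIONAL, DiseaseMode.GROUPED)),
    ("exact + disease + tier I",
     SearchStrategy(MatchClass.EXACT, DiseaseMode.GROUPED, Tier.I)),
]
coverage = cohort_coverage(cohort, store, [s for _, s in strategies],
                           load_ontology())
print("samples with >= 1 interpretation, aggregate store vs best single source:")
for i, (name, _) in enumerate(strategies):
    aggregate = coverage[i]["aggregate"]
    best = max(v for k, v in coverage[i].items() if k != "aggregate")
    print(f"  {name:26s} {100 * aggregate:5.1f}%   (best single source "
          f"{100 * best:5.1f}%)")
print("\nCoverage grows as the variant mode relaxes and shrinks as disease",
      "and evidence-tier constraints are added; the aggregate store always",
      "covers at least as much as any single knowledgebase.")
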