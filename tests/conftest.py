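import pytest

from metakb.pipeline import HarmonizationContext, harmonize_dumps
from metakb.synthetic import (CohortConfig, FixtureConfig,
                              generate_synthetic_cohort, generate_synthetic_kbs)


@pytest.fixture(scope="session")
def ctx():
    return HarmonizationContext.default()


@pytest.fixture(scope="session")
def kb_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("kbs")
    return generate_synthetic_kbs(FixtureConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def store(kb_paths, ctx):
    return harmonize_dumps(kb_paths, ctx).associations


@pytest.fixture(scope="session")
def table2_store(store):
    """The harmonized ERBB2 exon-20 duplication records embedded in the dumps."""
    return [a for a in store if "erbb2" in a.record_id]


@pytest.fixture(scope="session")
def cohort_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_synthetic_cohort(CohortConfig(n_samples=400, seed=7), outdir)
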