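import pytest
from hypothesis import HealthCheck, settings

from acetyldiff import SyntheticDesign
from acetyldiff.study import run_synthetic_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Seeds for the multi-seed end-to-end runs; fixed up front so every test
# sees the same cohorts and the suite is deterministic.
STUDY_SEEDS = list(range(100, 120))


@pytest.fixture(scope="session")
def default_studies():
    """Twenty end-to-end runs of the default synthetic design.

    Shared across validation tests; each entry is a StudyResult with
    peaks, classified domains, group profiles, enrichment and GWAS hits.
    """
    return [run_synthetic_study(SyntheticDesign(seed=s)) for s in STUDY_SEEDS]


@pytest.fixture(scope="session")
def tiny_design():
    """A small design for fast pipeline/file-level tests."""
    return SyntheticDesign(
        genome=(("chr1", 1_300_000), ("chr2", 900_000)),
        n_shared_peaks=4,
        n_induced_peaks=2,
        n_suppressed_peaks=1,
        seed=7,
    )
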