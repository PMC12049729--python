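import pandas as pd
import pytest

from immunoedit import (
    MutationTable,
    SelectionConfig,
    SubstitutionSpace,
    build_synthetic_coding_set,
    default_spectrum,
    simulate_baseline_cohort,
)
from immunoedit.regions import CodingRegion, CodingRegionSet


@pytest.fixture(scope="session")
def small_region_set():
    """Deterministic 60-nt CDS for exhaustive enumeration checks."""
    cds = "ATGGCTAAACTGCCGGATTACGTAGCACTGTGGAGGTTTGGCCATAACCAGATTCTGTAA"[:60]
    return CodingRegionSet([CodingRegion("T1", "chr1", "+", ((100, 160),), cds)])


@pytest.fixture(scope="session")
def small_space(small_region_set):
    return SubstitutionSpace(small_region_set)


@pytest.fixture(scope="session")
def synthetic_world():
    """Shared synthetic coding set + annotation + substitution space."""
    regions, annotation = build_synthetic_coding_set(
        total_length=9999, binder_fraction=0.3, seed=11
    )
    space = SubstitutionSpace(regions)
    return regions, annotation, space


@pytest.fixture(scope="session")
def baseline_cohort(synthetic_world):
    """Selection-free cohort: 40 samples x 300 mutations."""
    regions, annotation, space = synthetic_world
    config = SelectionConfig(n_samples=40, n_mutations=300, cds_length=9999, seed=7)
    return simulate_baseline_cohort(config, default_spectrum(), regions, annotation, space=space)


def make_table(rows: list[dict]) -> MutationTable:
    """Build a MutationTable from sparse row dicts (test helper)."""
    return MutationTable(pd.DataFrame(rows))


@pytest.fixture
def make_mutations():
    return make_table
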