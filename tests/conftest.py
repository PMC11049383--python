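import numpy as np
import pytest

from drscreen import (
    CohortSpec,
    CohortTable,
    FRFParams,
    build_default_partitions,
    fuzzify_cohort,
    generate_cohort,
    make_fixture,
    train_forest,
)


@pytest.fixture(scope="session")
def tiny_crisp():
    return make_fixture("tiny_crisp")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by training-path tests."""
    return generate_cohort(CohortSpec(n=400, seed=0)).cohort


@pytest.fixture(scope="session")
def small_evidence(small_cohort):
    parts = build_default_partitions(small_cohort)
    return fuzzify_cohort(small_cohort, parts)


@pytest.fixture(scope="session")
def small_forest(small_evidence):
    return train_forest(small_evidence, FRFParams(n_trees=5, seed=0))


def subset_cohort(cohort: CohortTable, mask: np.ndarray) -> CohortTable:
    return CohortTable(cohort.records[mask].reset_index(drop=True))
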