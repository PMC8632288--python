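import numpy as np
import pytest

from preemiegut.data_model import CountMatrix, SampleRecord, TaxonLineage
from preemiegut.synthetic import CohortSpec, simulate_cohort, simulate_null_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSpec(), seed=1)


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_null_cohort(CohortSpec(), seed=1)


@pytest.fixture
def tiny_matrix():
    """3 features x 2 samples with a small two-phylum taxonomy."""
    lineage = {
        "f1": TaxonLineage("PhyA", "FamA", "GenA", "sp1"),
        "f2": TaxonLineage("PhyA", "FamA", "GenB", "sp2"),
        "f3": TaxonLineage("PhyB", "FamB", "GenC", None),
    }
    return CountMatrix(
        features=["f1", "f2", "f3"],
        samples=["s1", "s2"],
        counts=np.array([[10, 0], [5, 2], [0, 8]]),
        lineage=lineage,
    )


@pytest.fixture
def weekly_samples():
    """One patient sampled every week 24-36."""
    return [SampleRecord(f"P1_w{w}", "P1", w) for w in range(24, 37)]
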