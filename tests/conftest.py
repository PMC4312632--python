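import numpy as np
import pytest

from metabostrat import PeakTable, SyntheticSpec, generate_cohort


@pytest.fixture
def tiny_table():
    """Hand-built 3-sample x 4-feature peak table, one internal standard."""
    return PeakTable(
        intensities=np.array(
            [[2.0, 3.0, 5.0, 10.0],
             [1.0, 1.0, 2.0, 10.0],
             [4.0, 4.0, 2.0, 10.0]]
        ),
        feature_ids=["A", "B", "C", "IS"],
        rt=np.array([1.0, 2.0, 3.0, 1.95]),
        mz=np.array([150.0, 250.0, 350.0, 200.0473]),
        sample_ids=["s1", "s2", "s3"],
        labels=np.array([0, 0, 1]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-signal cohort shared by slower integration tests."""
    spec = SyntheticSpec(
        n_class0=60, n_class1=20, n_features=30, n_informative=3,
        log2_effect=1.5, seed=11,
    )
    table, labels, truth = generate_cohort(spec)
    return table, labels, truth
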