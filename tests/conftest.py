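import logging

import numpy as np
import pytest

from phenotraj.core import ObservationTable
from phenotraj.simulation import BenchmarkSpec, generate_benchmark_data, generate_mosaic_like_cohort

logging.getLogger("phenotraj").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> ObservationTable:
    """A ~60-subject synthetic cohort shared by the slower integration tests."""
    return generate_mosaic_like_cohort(n_subjects=60, seed=11)


@pytest.fixture(scope="session")
def benchmark_data():
    """Default 5-state benchmark sample (750 sequences x 10 steps)."""
    return generate_benchmark_data(BenchmarkSpec(seed=7))


@pytest.fixture()
def tiny_table() -> ObservationTable:
    """Six encounters over two subjects with one binary label flip each."""
    return ObservationTable(
        subject_ids=np.array(["a", "a", "a", "b", "b", "b"], dtype=object),
        time_days=np.array([0.0, 100.0, 300.0, 0.0, 50.0, 400.0]),
        labels=np.array([0, 0, 1, 0, 1, 1]),
        features=np.array([[1.0, 0.0], [0.9, 0.1], [0.2, 0.8], [1.0, 0.1], [0.4, 0.9], [0.1, 1.0]]),
        feature_names=["f1", "f2"],
    )
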