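import numpy as np
import pytest

from ecipred import ActivityDataset, DatasetMetadata


@pytest.fixture
def toy_dataset() -> ActivityDataset:
    """3 enzymes x 2 chemicals with one missing cell, raw scale."""
    return ActivityDataset(
        enzyme_ids=("e1", "e2", "e3"),
        sequences=("ACDEFGHIKL", "ACDEFGHIKM", "MKLVXWYSTA"),
        chemical_ids=("c1", "c2"),
        smiles=("CCO", "c1ccccc1"),
        activity=np.array([[0.2, 5.0], [0.0, 0.1], [np.nan, 2.0]]),
        metadata=DatasetMetadata(name="toy", activity_threshold=0.5),
    )


@pytest.fixture
def binary_matrix_10x4() -> np.ndarray:
    """10 enzymes x 4 chemicals engineered for the balance filter:
    chemical counts are (1, 10, 5, 3)."""
    m = np.zeros((10, 4))
    m[0, 0] = 1  # count 1: fails count > 1
    m[:, 1] = 1  # count 10 = 100%: fails upper bound
    m[:5, 2] = 1  # count 5: retained
    m[:3, 3] = 1  # count 3: retained
    return m
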