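import numpy as np
import pytest

from sca_toolkit import ClusterAssignment, CountMatrix, RelationshipTable


@pytest.fixture
def toy_counts() -> CountMatrix:
    values = np.array(
        [
            [1, 0, 3, 5],
            [2, 3, 0, 4],
            [0, 0, 7, 1],
        ]
    )
    return CountMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def toy_relationships() -> RelationshipTable:
    return RelationshipTable({"TF1": {"g1", "g2"}, "TF2": {"g2", "g3"}})


@pytest.fixture
def toy_assignment() -> ClusterAssignment:
    return ClusterAssignment({"c1": "A", "c2": "A", "c3": "B", "c4": "B"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
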