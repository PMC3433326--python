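import numpy as np
import pytest

from hybriscope.io_model import MarkerMatrix, SampleRecord, SampleTable
from hybriscope.synthetic_data import SimConfig, simulate_dataset


def group_key(rec):
    """Cytotype-qualified taxon label used throughout the scenario tests."""
    if rec.taxon == "P. argentea" and rec.cytotype is not None:
        return f"{rec.taxon} {rec.cytotype}x"
    return rec.taxon


@pytest.fixture(scope="session")
def dataset():
    """The default simulated study scenario (seed 1), shared across tests."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture()
def tiny_matrix():
    return MarkerMatrix(
        ["s1", "s2", "s3"],
        ["L1", "L2", "L3"],
        np.array([[1, 1, 0], [0, 1, 1], [1, 1, 1]]),
    )


@pytest.fixture()
def tiny_meta():
    return SampleTable(
        [
            SampleRecord("s1", "A", "Pop1"),
            SampleRecord("s2", "B", "Pop1"),
            SampleRecord("s3", "A", "Pop2"),
        ]
    )
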