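import numpy as np
import pytest

from splicevb import SEExonStructure, SplicingCountData, effective_lengths_se


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def se_lengths():
    """Default skipped-exon effective lengths used across tests."""
    return effective_lengths_se(
        SEExonStructure(e1_len=500, e2_len=100, e3_len=500, read_len=100)
    )


def make_data(counts, lengths=None, cell_ids=None, event_ids=None):
    """Build a SplicingCountData from an (M, N, 3) array with unit-velocity
    lengths unless given."""
    counts = np.asarray(counts)
    M, N, _ = counts.shape
    if lengths is None:
        lengths = np.broadcast_to(
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), (N, 2, 3)
        ).copy()
    return SplicingCountData(
        cell_ids=cell_ids or [f"c{i}" for i in range(M)],
        event_ids=event_ids or [f"e{j}" for j in range(N)],
        counts=counts,
        lengths=lengths,
    )


@pytest.fixture
def data_factory():
    return make_data
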