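import numpy as np
import pytest

from ctcmarkers.io import CountMatrix


@pytest.fixture
def tiny_counts():
    """3 genes x 2 cells, handy for I/O and arithmetic checks."""
    return CountMatrix(
        counts=np.array([[5, 0], [0, 0], [0, 2]]),
        gene_ids=["G1", "G2", "G3"],
        cell_ids=["C1", "C2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
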