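import numpy as np
import pandas as pd
import pytest

from nanosig.ncounter import CountMatrix
from nanosig.signatures import (
    load_packaged_centroids,
    load_packaged_panel,
    load_packaged_signatures,
)


@pytest.fixture(scope="session")
def packaged_signatures():
    return load_packaged_signatures()


@pytest.fixture(scope="session")
def packaged_centroids():
    return load_packaged_centroids()


@pytest.fixture(scope="session")
def packaged_panel():
    return load_packaged_panel()


def make_count_matrix(endogenous, reference=None, negative=None, positive=None,
                      samples=None):
    """Small CountMatrix builder: each *-argument maps probe_id -> list of
    counts (one per sample)."""
    blocks = [
        (endogenous or {}, "endogenous"),
        (reference or {}, "reference"),
        (negative or {}, "negative"),
        (positive or {}, "positive"),
    ]
    rows, data = [], []
    for block, cls in blocks:
        for pid, counts in block.items():
            rows.append((pid, pid, cls))
            data.append(counts)
    n = len(data[0])
    samples = samples or [f"S{i+1}" for i in range(n)]
    probes = pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "probe_class"]
                          ).set_index("probe_id")
    counts = pd.DataFrame(np.asarray(data, dtype=float), index=probes.index,
                          columns=samples)
    return CountMatrix(probes=probes, counts=counts)


@pytest.fixture
def count_matrix_builder():
    return make_count_matrix
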