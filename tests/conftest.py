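import numpy as np
import pandas as pd
import pytest

from chromatrace.qc import UMICountMatrix


def make_matrix(counts, donor="donor1", time_point="t0", meta=None):
    """UMICountMatrix from a plain nested list / array with generated ids."""
    counts = np.asarray(counts)
    gene_ids = [f"G{i:05d}" for i in range(counts.shape[0])]
    cell_ids = [f"c{j:04d}" for j in range(counts.shape[1])]
    if meta is True:
        meta = pd.DataFrame(
            {
                "total_reads": [100_000] * counts.shape[1],
                "mito_fraction": [0.05] * counts.shape[1],
                "ercc_pearson": [0.9] * counts.shape[1],
            },
            index=cell_ids,
        )
    return UMICountMatrix(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
        donor=donor, time_point=time_point, cell_meta=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.integers(0, 20, size=(10, 8)))
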