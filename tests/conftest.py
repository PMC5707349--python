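import numpy as np
import pandas as pd
import pytest

from popclock.exprio import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, times=None, modality="sc"):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    meta = None
    if times is not None:
        meta = pd.DataFrame(
            {"time": np.asarray(times, dtype=float), "stage": "S1", "modality": modality},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
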