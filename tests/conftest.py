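import numpy as np
import pandas as pd
import pytest

from coexnet import synthio
from coexnet.exprfilter import ExpressionMatrix


@pytest.fixture(scope="session")
def planted_dataset():
    """Default-scale synthetic dataset: 500 genes, 10 blocks of 20, 12 samples."""
    matrix, truth = synthio.generate_expression(seed=7)
    genesets, truth = synthio.generate_genesets(
        truth, jitter=0.0, seed=8, universe=matrix.gene_ids
    )
    return matrix, genesets, truth


@pytest.fixture()
def tiny_matrix():
    """Hand-sized matrix with one perfectly duplicated profile."""
    df = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 1.0, 5.0],
            "s2": [2.0, 4.0, 3.0, 1.0],
            "s3": [3.0, 6.0, 2.0, 4.0],
            "s4": [4.0, 8.0, 6.0, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    return ExpressionMatrix(df)


def random_expression(n_genes, n_samples, seed):
    """Unstructured positive matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n_genes, n_samples))
    df = pd.DataFrame(
        values,
        index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df)
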