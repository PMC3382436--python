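import numpy as np
import pytest

from setlevel import ExpressionDataset, GeneSet, GeneSetCollection


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, balanced classes."""
    values = np.array(
        [
            [1.0, 3.0, 0.0, 2.0],
            [2.0, 2.0, 2.0, 2.0],
            [0.0, 1.0, 5.0, 4.0],
        ]
    )
    labels = {"s1": 0, "s2": 0, "s3": 1, "s4": 1}
    return ExpressionDataset(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], values, labels)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("A", frozenset({"g1", "g2"})),
            GeneSet("B", frozenset({"g2", "g3"})),
        ]
    )


def make_dataset(values, labels01, gene_prefix="g", sample_prefix="s"):
    """Build a dataset from a matrix and a 0/1 label list."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{j}" for j in range(values.shape[0])]
    samples = [f"{sample_prefix}{i}" for i in range(values.shape[1])]
    labels = {s: int(l) for s, l in zip(samples, labels01)}
    return ExpressionDataset(genes, samples, values, labels)
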