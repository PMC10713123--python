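import numpy as np
import pytest

from pride import ExpressionDataset, SSLPrior, standardize_within_group


@pytest.fixture
def tiny_dataset():
    """2 genes x 4 samples, two per group."""
    return ExpressionDataset(
        values=np.array([[1.0, 5.0], [2.0, 3.0], [4.0, 8.0], [6.0, 2.0]]),
        gene_names=("geneA", "geneB"),
        sample_ids=("s1", "s2", "s3", "s4"),
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def toy_dataset():
    """3 genes, 5 subjects per group, fixed values for hand computation."""
    rng = np.random.default_rng(7)
    values = np.round(rng.normal(size=(10, 3)), 3)
    return ExpressionDataset(
        values=values,
        gene_names=("g1", "g2", "g3"),
        sample_ids=tuple(f"s{i}" for i in range(10)),
        labels=np.array([0] * 5 + [1] * 5),
    )


@pytest.fixture
def toy_standardized(toy_dataset):
    return standardize_within_group(toy_dataset)


@pytest.fixture
def default_prior():
    return SSLPrior()
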