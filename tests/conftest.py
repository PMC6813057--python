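import numpy as np
import pandas as pd
import pytest

from reosig.io import ExpressionMatrix, LabelTable
from reosig.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with a clean g1>g2 pattern in the first two samples."""
    data = pd.DataFrame(
        {
            "s1": [5.0, 1.0, 2.0],
            "s2": [4.0, 2.0, 3.0],
            "s3": [1.0, 5.0, 2.0],
            "s4": [2.0, 4.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_labels() -> LabelTable:
    return LabelTable({"s1": "MSI", "s2": "MSI", "s3": "MSS", "s4": "MSS"})


@pytest.fixture
def planted_dataset():
    """Default planted cohort: 10 pairs at p_pattern 0.95/0.05, n=60/60."""
    config = SimulationConfig(seed=7)
    matrix, labels, planted = simulate_dataset(config)
    return matrix, labels, planted, config


def make_two_class_matrix(rng, n_genes, n_shifted, shift, n_per_class):
    """Gaussian matrix where the first n_shifted genes are mean-shifted in class 1."""
    X = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_class))
    X[:n_shifted, :n_per_class] += shift
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"a{i}" for i in range(n_per_class)] + [
        f"b{i}" for i in range(n_per_class)
    ]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
    labels = LabelTable(
        {s: ("MSI" if s.startswith("a") else "MSS") for s in samples}
    )
    return matrix, labels
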