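import numpy as np
import pytest

from sandcatfs import (
    LabeledExpression,
    SyntheticSpec,
    make_synthetic_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale planted-signal dataset: 40 samples, 30 genes, 4 planted."""
    return make_synthetic_expression(
        SyntheticSpec(n_samples=40, n_genes=30, n_informative=4,
                      effect_size=2.5, class_balance=0.6, seed=7)
    )


@pytest.fixture(scope="session")
def small_data(small_truth):
    return small_truth.matrix


@pytest.fixture
def separable_data():
    """One perfectly separating gene (column 0) among pure noise."""
    gen = np.random.default_rng(99)
    n = 40
    y = np.array([0] * 20 + [1] * 20)
    X = gen.normal(size=(n, 5))
    X[:, 0] = np.where(y == 1, 5.0, -5.0) + gen.normal(0, 0.1, size=n)
    return LabeledExpression(
        values=X,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(5)],
        labels=["pos" if v else "neg" for v in y],
    )
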