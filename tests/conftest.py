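import numpy as np
import pytest

from pcnet.core_io import ExpressionMatrix


def make_expression(values: np.ndarray) -> ExpressionMatrix:
    """Wrap a raw genes x samples array with generated ids."""
    n_genes, n_samples = values.shape
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(n_genes)),
        tuple(f"s{j}" for j in range(n_samples)),
        values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_expression(rng):
    return make_expression(rng.normal(size=(30, 20)))
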