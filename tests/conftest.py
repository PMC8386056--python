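import numpy as np
import pytest

from fuseprio.core import ExpressionMatrix, PathogenicLabels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression(rng):
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=[f"s{j}" for j in range(5)],
        values=rng.standard_normal((8, 5)),
    )


@pytest.fixture
def toy_labels():
    genes = [f"g{i}" for i in range(8)]
    return PathogenicLabels(genes, np.array([1, 1, 0, 0, 0, 0, 1, 0]))
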