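import numpy as np
import pytest

from survformer.io_preprocess import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr():
    """4 samples x 3 genes, simple increasing values."""
    return ExpressionMatrix(
        ["S1", "S2", "S3", "S4"],
        ["GA", "GB", "GC"],
        np.array([[0.0, 1.0, 3.0], [1.0, 3.0, 7.0], [3.0, 7.0, 15.0], [7.0, 15.0, 31.0]]),
    )
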