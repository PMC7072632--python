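import numpy as np
import pandas as pd
import pytest

from ecvnet.data import ExpressionMatrix
from ecvnet.local_model import ScoreConfig


def make_matrix(columns: dict, prefix: str = "s") -> ExpressionMatrix:
    """Samples x genes matrix from {gene: value-array}."""
    n = len(next(iter(columns.values())))
    return ExpressionMatrix(
        pd.DataFrame(columns, index=[f"{prefix}{i}" for i in range(n)])
    )


@pytest.fixture(scope="session")
def cfg() -> ScoreConfig:
    return ScoreConfig()


@pytest.fixture(scope="session")
def linear_pair() -> ExpressionMatrix:
    """Noise-free y = 2x on 300 samples."""
    x = np.random.default_rng(7).uniform(0.0, 1.0, 300)
    return make_matrix({"x": x, "y": 2.0 * x})
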