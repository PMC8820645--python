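import numpy as np
import pandas as pd
import pytest

from crossomics import ConfounderTable, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """A tiny sample-aligned pair of matrices."""
    n, p, q = 40, 6, 8
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    ids = [f"s{i}" for i in range(n)]
    x = OmicsMatrix(X, ids, [f"x{j}" for j in range(p)])
    y = OmicsMatrix(Y, ids, [f"y{j}" for j in range(q)])
    return x, y


@pytest.fixture
def confounders():
    idx = [f"s{i}" for i in range(6)]
    return ConfounderTable(
        frame=pd.DataFrame(
            {"age": [40.0, 50.0, 60.0, 45.0, 55.0, 65.0],
             "sex": ["f", "m", "f", "m", "f", "m"]},
            index=idx,
        )
    )
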