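import numpy as np
import pandas as pd
import pytest

from hasrna.core import CountMatrix, Hybrid, MatingDesign


@pytest.fixture
def tiny_design() -> MatingDesign:
    """2 x 2 factorial with hand-set MPH values."""
    parents = [("A1", "A"), ("A2", "A"), ("B1", "B"), ("B2", "B")]
    hybrids = [
        Hybrid("A1xB1", "A1", "B1", 70.0),
        Hybrid("A1xB2", "A1", "B2", 80.0),
        Hybrid("A2xB1", "A2", "B1", 100.0),
        Hybrid("A2xB2", "A2", "B2", 110.0),
    ]
    return MatingDesign(parents, hybrids)


@pytest.fixture
def random_raw_matrix() -> CountMatrix:
    rng = np.random.default_rng(7)
    X = rng.poisson(4.0, size=(40, 5)).astype(float)
    df = pd.DataFrame(X, columns=[f"L{j}" for j in range(5)])
    df.index = [f"s{i}" for i in range(40)]
    return CountMatrix(df, stage="raw")
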