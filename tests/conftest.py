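import numpy as np
import pandas as pd
import pytest

from rhythmbench.matrix import ExpressionMatrix, SampleDesign
from rhythmbench.methods import MethodConfig


@pytest.fixture(scope="session")
def design24():
    """24 time points every 2 h over two 24 h cycles."""
    return SampleDesign.regular(24, 2.0)


@pytest.fixture(scope="session")
def design12():
    """12 time points every 2 h over one cycle."""
    return SampleDesign.regular(12, 2.0)


@pytest.fixture()
def fast_cfg():
    """Method config small enough for unit tests."""
    return MethodConfig(seed=7, n_permutations=200, null_size=20000)


@pytest.fixture()
def tiny_matrix(design12):
    rng = np.random.default_rng(0)
    vals = rng.lognormal(5, 1, size=(8, design12.n_samples))
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(8)],
                      columns=design12.labels())
    return ExpressionMatrix(df, design12)
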