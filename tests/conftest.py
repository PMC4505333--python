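import numpy as np
import pandas as pd
import pytest

from sigmatch.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix():
    """3 probes x 2 samples with values 1..6."""
    data = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=pd.Index(["A", "B", "C"], name="probe_id"),
    )
    return ExpressionMatrix(data)
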