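import numpy as np
import pandas as pd
import pytest

from pdmg.io_formats import CountMatrix
from pdmg.synthetic_data import make_truth


@pytest.fixture
def small_truth():
    """Compact universe for fast end-to-end tests."""
    return make_truth({"seed": 1, "n_signature": 10, "n_genes": 500})


@pytest.fixture
def toy_counts():
    values = np.array(
        [
            [100, 1000],
            [200, 200],
            [300, 300],
            [400, 400],
            [500, 500],
            [600, 600],
            [700, 700],
            [800, 800],
        ]
    )
    return CountMatrix(values, [f"g{i}" for i in range(8)], ["a", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
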