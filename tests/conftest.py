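import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_matrix(rng):
    """200 features x 40 samples, first 20 features shifted by 2 in group A."""
    x = pd.DataFrame(
        rng.standard_normal((200, 40)),
        index=[f"f{i:03d}" for i in range(200)],
        columns=[f"s{j:02d}" for j in range(40)],
    )
    x.iloc[:20, :20] += 2.0
    labels = pd.Series(["A"] * 20 + ["B"] * 20, index=x.columns)
    return x, labels
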