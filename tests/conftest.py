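import numpy as np
import pandas as pd
import pytest

from pufedboost.data import SampleTable


def make_table(n=20, d=5, seed=0, with_y=True, pos_fraction=0.5):
    """Small random sample table with ids R000..; labels drawn Bernoulli."""
    rng = np.random.default_rng(seed)
    features = pd.DataFrame(
        rng.standard_normal((n, d)),
        columns=[f"f{i}" for i in range(d)],
        index=pd.Index([f"R{i:03d}" for i in range(n)], name="sample_id"),
    )
    y = (rng.random(n) < pos_fraction).astype(np.int8) if with_y else None
    s = np.zeros(n, dtype=np.int8)
    if with_y:
        labeled = (y == 1) & (rng.random(n) < 0.5)
        s[labeled] = 1
    return SampleTable(features=features, s=s, y=y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return make_table(n=40, d=6, seed=3)
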