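import numpy as np
import pytest

from ssdfs.synthetic import SyntheticSpec, generate_table
from ssdfs.tabular import standardize, stratified_split


@pytest.fixture(scope="session")
def small_table():
    """200x8 table: 2 informative columns (sep=3), 6 noise, balanced labels."""
    return generate_table(SyntheticSpec(200, 2, 0, 6, 3.0, 0.1, seed=11))


@pytest.fixture(scope="session")
def small_split(small_table):
    table, _ = small_table
    raw = stratified_split(table, 0.2, seed=0)
    return standardize(raw.train, raw.test)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
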