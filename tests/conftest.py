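import numpy as np
import pytest

from micropart import CountTable, SampleMetadata
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array([[5, 0, 3],
                       [1, 2, 0],
                       [10, 10, 10]])
    return CountTable(["otuA", "otuB", "otuC"], ["s1", "s2", "s3"], counts,
                      taxonomy={"otuA": "k__Bacteria; p__Firmicutes"})


@pytest.fixture
def small_metadata():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "sex": ["male", "female", "male", "female"],
        "cage": ["c1", "c1", "c2", "c2"],
        "adg": [30.0, 28.5, 35.2, 31.0],
    }))
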