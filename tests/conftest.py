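import numpy as np
import pytest

from mnlnet.preprocessing import segment_records
from mnlnet.synthetic import SyntheticSpec, generate_bonn_like


@pytest.fixture(scope="session")
def small_records():
    """Five sets x 4 records at full record length, moderate separability."""
    return generate_bonn_like(SyntheticSpec(n_records_per_set=4, seed=11))


@pytest.fixture(scope="session")
def small_segments(small_records):
    return segment_records(small_records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
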