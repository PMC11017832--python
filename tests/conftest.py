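import pytest

from pfindex.datagen import default_index_parameters
from pfindex.index import IndexParameters


@pytest.fixture(scope="session")
def calibrated_params() -> IndexParameters:
    """Index parameters calibrated to the published marginal statistics."""
    return default_index_parameters()


@pytest.fixture()
def simple_params() -> IndexParameters:
    """Round-number parameters for hand-checkable arithmetic."""
    return IndexParameters(b0=1.0, b1=0.01, c0=0.5, c1=0.02)
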