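import pytest

from crosswise.datasets import STREET_CROSSING_DESIGN, street_crossing_counts


@pytest.fixture
def canonical_counts():
    """Reconstructed answer frequencies of the street-crossing study."""
    return street_crossing_counts()


@pytest.fixture
def design158():
    return STREET_CROSSING_DESIGN
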