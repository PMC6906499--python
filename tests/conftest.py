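import pytest

from targetodds.core import SampleSpace, TestParams

# the TestParams dataclass is a domain type, not a test container
TestParams.__test__ = False


@pytest.fixture(scope="session")
def base_space() -> SampleSpace:
    """The base-case sample space: 20,000 genes, 10,000 diseases,
    4,000 druggable genes, 100 causal genes per disease."""
    return SampleSpace()
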