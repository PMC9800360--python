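import pytest

from glinet import worked_example_constants, worked_example_graph


@pytest.fixture(scope="session")
def wg():
    """The reconstructed 15-node walkthrough network."""
    return worked_example_graph()


@pytest.fixture(scope="session")
def wc():
    """The published walkthrough constants."""
    return worked_example_constants()
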