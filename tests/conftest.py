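import pytest

from tangleasm import worked_example_graph


@pytest.fixture
def line15011():
    """The five-node line A..E with copy numbers (1, 1, 0, 1, 1)."""
    return worked_example_graph(node_length=60, seed=11)
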