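import pytest

from nanograft.synthetic_panel import make_panel

FRAMEWORKS = ("FW1", "FW2", "FW3", "FW4")


@pytest.fixture(scope="session")
def panel():
    """The seven synthetic humanization-panel constructs."""
    return make_panel()


@pytest.fixture(scope="session")
def frameworks():
    return FRAMEWORKS
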