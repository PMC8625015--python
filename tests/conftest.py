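import pytest

from microhdx.synthetic_data import fixture_library


@pytest.fixture(scope="session")
def panel():
    """Reference compound fixtures keyed by name."""
    return {fx.name: fx for fx in fixture_library()}
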