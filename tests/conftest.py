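import pytest

from psifold import default_model


@pytest.fixture(scope="session")
def model():
    """Shipped toy energy model (kT = 0.61633, theta = 3, cap = 30)."""
    return default_model()
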