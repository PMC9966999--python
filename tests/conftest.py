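import pytest

from cyp17space.synthetic import make_paper_shaped_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    """The noise-free paper-shaped synthetic dataset (seed 42), shared."""
    return make_paper_shaped_fixture(seed=42)
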