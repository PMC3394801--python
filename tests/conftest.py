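import pytest
from hypothesis import settings

from decaaf import build_template, make_anchor_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def hne():
    """Elastase (1B0F) anchor fixture: Ser195/OG, His57/ND1, Ser214/OG."""
    return make_anchor_fixture("hne_1b0f")


@pytest.fixture
def p14a():
    """P14A (1CFE) anchor fixture: Ser49/OG, His48/ND1, Tyr36/OH."""
    return make_anchor_fixture("p14a_1cfe")


@pytest.fixture
def hne_motif(hne):
    return build_template(hne, ["Ser195", "His57", "Ser214"])
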