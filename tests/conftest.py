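import pytest

from conjubot import generate_fixture_design, generate_heatshock_fixture


@pytest.fixture
def small_design():
    """2 donors x 3 recipients, 12 reactions."""
    return generate_fixture_design(seed=11, n_ecoli=2, n_strep=3, n_reactions=12)


@pytest.fixture
def full_design():
    """Maximum-capacity conjugation design: 18 x 30, 192 reactions."""
    return generate_fixture_design(seed=7, n_ecoli=18, n_strep=30, n_reactions=192)


@pytest.fixture
def heatshock_design():
    return generate_heatshock_fixture(seed=1)
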