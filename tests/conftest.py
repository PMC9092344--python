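import numpy as np
import pytest

from cgrnet import (FixtureSpec, fig1_water_example, generate_toy_reactions,
                    parse_reaction)

WATER_BALANCED = "[H:1][O:2][H:3]>>[O-:2][H:3].[H+:1]"
WATER_IMBALANCED = "[H:1][O:2][H:3]>>[O-:2][H:3]"


@pytest.fixture(scope="session")
def water_records():
    return fig1_water_example()


@pytest.fixture(scope="session")
def identity_record():
    return parse_reaction("[CH4:1]>[Na+]>[CH4:1]")


@pytest.fixture(scope="session")
def toy_records():
    """50 mixed balanced/imbalanced toy reactions with targets."""
    return generate_toy_reactions(
        FixtureSpec(n_reactions=50, seed=7, fraction_imbalanced=0.3))


@pytest.fixture(scope="session")
def balanced_records():
    return generate_toy_reactions(
        FixtureSpec(n_reactions=30, seed=5, fraction_imbalanced=0.0))
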