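import numpy as np
import pytest

from pulsa_screen.counting import AmpliconDesign
from pulsa_screen.screen_model import assign_effects, generate_library, simulate_population


@pytest.fixture(scope="session")
def small_library():
    """25 genes x 4 guides + 100 NTCs, 20-nt spacers."""
    return generate_library(25, 4, 100, seed=11)


@pytest.fixture(scope="session")
def null_truth(small_library):
    return assign_effects(small_library, 0, 0, base_logit=-2.2, seed=11)


@pytest.fixture(scope="session")
def null_population(null_truth):
    return simulate_population(null_truth, 20_000, seed=11)


@pytest.fixture(scope="session")
def toy_design():
    return AmpliconDesign(left_flank="ACCG", right_flank="GTTT", spacer_length=5)
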