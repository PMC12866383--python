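import numpy as np
import pytest

from boindosim import BoinDesign, DosimetryConfig
from boindosim.synthdata import default_scenario
from boindosim.trial import build_ladder


@pytest.fixture
def design():
    """Default design: phi = 0.25, caps 9 per level / 36 total."""
    return BoinDesign()


@pytest.fixture
def dosimetry_config():
    return DosimetryConfig()


@pytest.fixture
def three_level_ladder():
    """Step-up rung (1.85 then 5.55 GBq x 3) plus 9.25 and 11.1 GBq rungs."""
    return build_ladder(
        [
            {"cycle1_activity_gbq": 1.85, "later_cycle_activity_gbq": 5.55,
             "planned_cycles": 4},
            {"cycle1_activity_gbq": 9.25, "planned_cycles": 3},
            {"cycle1_activity_gbq": 11.1, "planned_cycles": 3},
        ]
    )


@pytest.fixture
def noiseless_scenario():
    return default_scenario(noise_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
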