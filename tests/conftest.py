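import logging

import pytest
from hypothesis import settings

from paleokaryo.simulate import EvolutionScenario, run_scenario

logging.disable(logging.INFO)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def two_wgd_result():
    """A small two-WGD history with outgroup, pre-1R, post-1R and post-2R branches."""
    scenario = EvolutionScenario(
        3,
        60,
        [
            {"type": "branch", "name": "out", "loss_rate": 0.0},
            {"type": "branch", "name": "pre1r", "loss_rate": 0.0},
            {"type": "wgd", "multiplicity": 2},
            {"type": "branch", "name": "cyclo", "loss_rate": 0.0},
            {"type": "wgd", "multiplicity": 2},
            {"type": "branch", "name": "shark", "loss_rate": 0.0},
            {"type": "speciate", "names": ["gar", "chicken"], "loss_rate": 0.0},
        ],
        seed=7,
    )
    return run_scenario(scenario)
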