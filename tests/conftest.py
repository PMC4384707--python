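import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from atdose.diffexpr import call_all_conditions
from atdose.simulate import SimulationDesign, gen_expression

logging.getLogger("atdose").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_design():
    return SimulationDesign(seed=211)


@pytest.fixture(scope="session")
def default_study(default_design):
    """The default synthetic study (matrix + truth), generated once."""
    return gen_expression(default_design)


@pytest.fixture(scope="session")
def default_calls(default_study):
    """DE calls for every condition of the default synthetic study."""
    study, _ = default_study
    return call_all_conditions(study)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150128)
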