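import logging

import numpy as np
import pytest

from vasapf.params import MaterialParams, VVTreeParams
from vasapf.vv_geometry import make_fixture

logging.getLogger("vasapf").setLevel(logging.ERROR)


@pytest.fixture
def mat():
    return MaterialParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture("small")


@pytest.fixture
def tree_params():
    return VVTreeParams(angle_jitter=0.0, seed=7)


# -- shared scenario runs (expensive; computed once per session) ------------

@pytest.fixture(scope="session")
def athero_run():
    from vasapf.scenarios import run_scenario, scenario_preset
    return run_scenario(scenario_preset("atherosclerosis", "small"))


@pytest.fixture(scope="session")
def dissection_run():
    from vasapf.scenarios import run_scenario, scenario_preset
    return run_scenario(scenario_preset("dissection", "small"))
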