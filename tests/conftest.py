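import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lexddm.params import REFERENCE_PARAMS, DiffusionParams
from lexddm.simulate import DesignSpec, generate_experiment


@pytest.fixture(scope="session")
def ref_params():
    return REFERENCE_PARAMS


@pytest.fixture
def wn_params():
    """The nonrepeated-word condition parameter set."""
    return REFERENCE_PARAMS[("word", "nonrepeated")]


@pytest.fixture
def plain_params():
    """A single-trial kernel without variability or contaminants."""
    return DiffusionParams(v=0.32, a=0.10, zr=0.54, t_er=0.406)


@pytest.fixture(scope="session")
def sim_experiment():
    """One synthetic experiment at the reference generating parameters."""
    trials, meta = generate_experiment(DesignSpec(), REFERENCE_PARAMS, 1234)
    return trials, meta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987)
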