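import numpy as np
import pytest

from ecg2img.imaging import RenderConfig
from ecg2img.leads import select_panel
from ecg2img.synthetic import SynthParams, gen_patient


@pytest.fixture(scope="session")
def render_config() -> RenderConfig:
    return RenderConfig()


@pytest.fixture(scope="session")
def synth_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def survivor_record(synth_params):
    return gen_patient(label=0, seed=101, params=synth_params,
                       patient_id="fix_s0")


@pytest.fixture(scope="session")
def nonsurvivor_record(synth_params):
    return gen_patient(label=1, seed=202, params=synth_params,
                       patient_id="fix_n0")


@pytest.fixture(scope="session")
def survivor_panel(survivor_record):
    return select_panel(survivor_record)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
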