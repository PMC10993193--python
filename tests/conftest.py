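import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trpthermo as tp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rptrpa5b():
    return tp.preset_gating("RpTRPA5B")


@pytest.fixture(scope="session")
def default_plant():
    return tp.HeatingPlant()


@pytest.fixture(scope="session")
def default_gains():
    return tp.PIDGains()


@pytest.fixture(scope="session")
def step_protocol():
    """The standard 12-step 23.5–71.7 °C, 700-ms, 10-kHz protocol."""
    return tp.StimulusProtocol.temperature_steps()


def _cohort(preset):
    cfg = tp.PipelineConfig(preset=preset, n_cells=8, seeds=tuple(range(1, 9)),
                            noise_sd_fraction=0.02)
    return tp.run_pipeline(cfg)


@pytest.fixture(scope="session")
def rptrpa5b_cohort():
    """8-cell RpTRPA5B cohort, 2% noise, seeds 1–8, full pipeline."""
    return _cohort("RpTRPA5B")


@pytest.fixture(scope="session")
def trpv1_cohort():
    return _cohort("rTRPV1")


@pytest.fixture(scope="session")
def dtrpa1d_cohort():
    return _cohort("dTRPA1D")


@pytest.fixture(scope="session")
def noiseless_recording():
    """Single noiseless RpTRPA5B recording with its calibration sweeps."""
    cell = tp.preset_cell("RpTRPA5B", noise_sd_fraction=0.0)
    protocol = tp.StimulusProtocol.temperature_steps()
    rec = tp.synthesize_cell_recording(cell, protocol, seed=1)
    return cell, rec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
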