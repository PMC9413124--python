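import pytest

from pulsebp import pipeline, sensor_sim
from pulsebp.config import PipelineConfig


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def noiseless_cfg() -> PipelineConfig:
    cfg = PipelineConfig()
    return cfg.model_copy(
        update={"simulation": cfg.simulation.model_copy(update={"snr_db": None})}
    )


def short_cfg(base: PipelineConfig, duration: float = 15.0,
              **sim_updates) -> PipelineConfig:
    sim = base.simulation.model_copy(
        update={"duration_s": duration, **sim_updates})
    return base.model_copy(update={"simulation": sim})


@pytest.fixture(scope="session")
def cohort5():
    return sensor_sim.make_cohort(5, 42)


@pytest.fixture(scope="session")
def profile(cohort5):
    return cohort5[0]


@pytest.fixture(scope="session")
def noiseless_session(profile, noiseless_cfg):
    return pipeline.simulate_session(profile, noiseless_cfg, session_index=0)


@pytest.fixture(scope="session")
def noisy_session(profile, default_cfg):
    return pipeline.simulate_session(profile, default_cfg, session_index=0)
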