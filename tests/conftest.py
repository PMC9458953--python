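"""Shared fixtures: scenario configs and one cached noiseless reference run."""

import pytest
from hypothesis import HealthCheck, settings

import lfcr
from lfcr import pipeline

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def lactate_cfg():
    return pipeline.scenario("lactate_2L")


@pytest.fixture(scope="session")
def noiseless_run(lactate_cfg):
    """Noiseless 30->10 degC staged run of the calibrated 2 L lactate reactor."""
    cfg = lactate_cfg
    return lfcr.simulate(cfg.feed, cfg.params, cfg.schedule, noise_cv=0.0,
                         seed=11, volume=cfg.volume, dt=cfg.dt)


@pytest.fixture(scope="session")
def noiseless_summaries(lactate_cfg, noiseless_run):
    return lfcr.stage_summaries(noiseless_run.samples, lactate_cfg.feed,
                                lactate_cfg.schedule)


@pytest.fixture(scope="session")
def short_schedule():
    """One warm stage, small enough for per-test simulations."""
    return lfcr.Schedule(stages=((30.0, 2.0),), burn_in=1.0, sample_interval=12.0)
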