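import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from baroimu import quaternion as quat
from baroimu.evaluation import run_validation_suite
from baroimu.sensor_model import FusionConfig, RestStatistics


@pytest.fixture
def cfg_a() -> FusionConfig:
    return FusionConfig.for_method("A")


@pytest.fixture
def cfg_b() -> FusionConfig:
    return FusionConfig.for_method("B")


@pytest.fixture
def level_rest() -> RestStatistics:
    """Rest statistics of a perfectly level, bias-free sensor."""
    return RestStatistics(gyro_bias=np.zeros(3), baro_baseline=0.0,
                          initial_quaternion=quat.identity(),
                          mean_accel=np.array([0.0, 0.0, -9.81]))


@pytest.fixture(scope="session")
def validation_suite():
    """Full simulated validation campaign (all scenarios, 10 seeds, both
    conditioning methods).  Computed once per session; only the accuracy
    acceptance tests request it."""
    return run_validation_suite(base_seed=1, n_trials=10, duration=180.0)
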