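import numpy as np
import pytest

from ergoload.pipeline import PipelineConfig, run_day_pipeline
from ergoload.simulate import DayScenario, default_event_schedule, generate_day


def day_recordings(day):
    return {
        "emg": day.emg,
        "imu_back": day.imu_back,
        "imu_thigh": day.imu_thigh,
        "heart": day.heart,
    }


@pytest.fixture(scope="session")
def small_day():
    """A 20-minute synthetic working day with 8 scripted overload episodes."""
    rng = np.random.default_rng(11)
    scenario = DayScenario(
        duration_s=1200.0,
        seed=7,
        events=default_event_schedule(8, 1200.0, rng=rng),
    )
    return generate_day(scenario)


@pytest.fixture(scope="session")
def small_day_result(small_day):
    return run_day_pipeline(day_recordings(small_day), small_day.annotations, PipelineConfig())
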