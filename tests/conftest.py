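import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import handpilot as hp
from handpilot.synth import IMU_ACTION_CLASS

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[
        HealthCheck.too_slow,
        # fixtures used inside @given are immutable value objects
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def emg_config():
    return hp.EmgSynthConfig(seed=1)


@pytest.fixture(scope="session")
def emg_calibration(emg_config):
    rest, vc = hp.synth_emg_calibration(emg_config)
    return hp.calibrate_emg(rest, vc)


@pytest.fixture(scope="session")
def imu_config():
    return hp.ImuSynthConfig(seed=1, drop_prob=0.1)


@pytest.fixture(scope="session")
def imu_calibrated(imu_config):
    """(thresholds, model) fitted on a labelled synthetic calibration session."""
    stream, truth = hp.synth_imu_calibration(imu_config)
    return hp.calibrate_imu(
        stream,
        [gt.time for gt in truth],
        [int(IMU_ACTION_CLASS[gt.action]) for gt in truth],
    )


@pytest.fixture
def default_thresholds():
    """Hysteresis ratios at the calibration defaults, unit VC."""
    return hp.EmgCalibration(vc1=1.0, vc2=1.0, rl1=0.2, rh1=0.6, rl2=0.2, rh2=0.6)


def make_burst_stream(
    move_times, classes, duration, config=None, seed=7
) -> tuple[hp.ImuStream, list]:
    """Synthetic IMU session with movements of the given classes."""
    config = config or hp.ImuSynthConfig(seed=seed)
    if config.seed != seed:
        config = hp.ImuSynthConfig(**{**config.__dict__, "seed": seed})
    instrs = [
        hp.Instruction(t, f"movement{int(c)}") for t, c in zip(move_times, classes)
    ]
    return hp.synth_imu_session(
        hp.ScriptedSession(instrs, duration=duration), config
    )
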