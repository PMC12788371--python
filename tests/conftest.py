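import numpy as np
import pytest

from copmat.sensor_sim import (
    NoiseModel,
    default_camera_pair,
    default_protocols,
    make_cohort,
    simulate_trial,
)
from copmat.sync_assemble import TrialRecord
from copmat.tactile_pipeline import SensorGeometry


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry()


@pytest.fixture(scope="session")
def cameras(geometry):
    return default_camera_pair(geometry)


@pytest.fixture(scope="session")
def subject():
    return make_cohort(1, seed=42)[0]


@pytest.fixture(scope="session")
def short_protocols():
    """Desk-size protocols: 12 s trials, middle 8 s analyzed."""
    return default_protocols(duration_s=12.0, analysis_window_s=8.0)


@pytest.fixture(scope="session")
def ideal_walk_trial(subject, short_protocols, geometry, cameras):
    return simulate_trial(subject, short_protocols["walk_in_place"],
                          NoiseModel.ideal(), geometry, seed=3,
                          cam_a=cameras[0], cam_b=cameras[1])


@pytest.fixture(scope="session")
def ideal_squat_trial(subject, short_protocols, geometry, cameras):
    return simulate_trial(subject, short_protocols["squat"],
                          NoiseModel.ideal(), geometry, seed=4,
                          cam_a=cameras[0], cam_b=cameras[1])


def make_fake_record(T=56, subject_id="S000", protocol_id=1, seed=0,
                     cop_scale=50.0):
    """A small synthetic TrialRecord without running the simulator."""
    rng = np.random.default_rng(seed)
    truth = 300.0 + cop_scale * rng.standard_normal((T, 2)).cumsum(axis=0) / np.sqrt(T)
    frames = rng.integers(0, 255, size=(T, 64, 64), dtype=np.uint8)
    return TrialRecord(
        tactile_gray8=frames,
        tactile_wma_cop=truth + rng.normal(0, 5, (T, 2)),
        truth_cop=truth,
        angular_features=rng.normal(0, 1, (T, 18)),
        subject_features=rng.normal(0, 1, 6),
        subject_id=subject_id,
        protocol_id=protocol_id,
        sensor_width_mm=600.0,
        sensor_length_mm=800.0,
        timestamps=np.arange(T) / 14.0,
    )
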