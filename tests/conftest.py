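import numpy as np
import pytest

from sts2walk import KinematicParams, synth


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free 23-cycle recording with ground truth (cohort-median cadence)."""
    params = KinematicParams(
        n_cycles=23,
        stand_duration=0.8,
        sit_duration=0.8,
        dwell_stand=0.45,
        dwell_sit=0.45,
        max_trunk_lean=25.0,
        peak_acc=1.4,
        noise_sd_acc=0.0,
        noise_sd_gyro=0.0,
        seed=0,
    )
    return synth.simulate_recording(params)


@pytest.fixture(scope="session")
def noisy_recording():
    """Moderate-noise recording with ground truth."""
    params = KinematicParams(
        n_cycles=18,
        stand_duration=1.1,
        sit_duration=1.0,
        dwell_stand=0.5,
        dwell_sit=0.6,
        max_trunk_lean=30.0,
        peak_acc=1.45,
        noise_sd_acc=0.05,
        noise_sd_gyro=2.0,
        seed=11,
    )
    return synth.simulate_recording(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_recording_csv(path, t, acc, gyro, subject_id="T01", fs=100.0, units=None):
    """Write a recording file by hand, bypassing the library writer."""
    units = units or {}
    with open(path, "w") as fh:
        fh.write(f"# subject_id={subject_id}\n")
        fh.write(f"# fs={fs:g}\n")
        for key, val in units.items():
            fh.write(f"# {key}={val}\n")
        fh.write("t,ax,ay,az,gx,gy,gz\n")
        for i in range(len(t)):
            row = [t[i], *acc[i], *gyro[i]]
            fh.write(",".join(f"{v:.9g}" for v in row) + "\n")
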