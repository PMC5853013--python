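import numpy as np
import pytest

from pdmotor.recording import SensorRecording


def make_recording(gyro, fs=128.0, task="finger_tapping", **meta):
    """Recording from a (3, N) gyro array with zero acceleration."""
    gyro = np.atleast_2d(np.asarray(gyro, dtype=float))
    n = gyro.shape[1]
    return SensorRecording(
        sample_rate=fs, t=np.arange(n) / fs, gyro=gyro,
        accel=np.zeros((3, n)), task=task, **meta,
    )


def sine_recording(freq, fs=128.0, duration=30.0, amplitude=1.0, axis=1,
                   task="finger_tapping"):
    t = np.arange(0.0, duration, 1.0 / fs)
    gyro = np.zeros((3, t.size))
    gyro[axis] = amplitude * np.sin(2 * np.pi * freq * t)
    return make_recording(gyro, fs=fs, task=task)


@pytest.fixture
def noiseless_tapping():
    """15-cycle noiseless finger-tapping simulation at 2 Hz, 100 deg/s."""
    from pdmotor.synthetic import SimulationParams, simulate_recording

    return simulate_recording(SimulationParams(base_rate=2.0,
                                               base_amplitude=100.0, seed=1))
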