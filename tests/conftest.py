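import numpy as np
import pytest

from shoalforage.kinematics import TrajectoryRecording


def straight_recording(speed: float = 4.0, n: int = 200, k: int = 1,
                       frame_rate: float = 50.0,
                       direction=(1.0, 0.0)) -> TrajectoryRecording:
    """Uniform straight-line motion starting near the arena center."""
    times = np.arange(n) / frame_rate
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pos = np.zeros((n, k, 2))
    for j in range(k):
        start = np.array([-8.0 + 2.0 * j, -8.0])
        pos[:, j] = start + np.outer(times * speed, d)
    return TrajectoryRecording(times=times, positions=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
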