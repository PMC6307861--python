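import numpy as np
import pytest

from smtf.tracking import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_trajectory(tid, frames, xy, dt=0.01, exposure=0.0):
    return Trajectory(
        id=tid,
        frames=np.asarray(frames),
        xy=np.asarray(xy, float),
        frame_interval=dt,
        exposure=exposure,
    )


def trajectories_with_durations(n_frames_list, dt=0.5):
    """Immobile trajectories with prescribed observed frame counts."""
    out = []
    for i, k in enumerate(n_frames_list):
        k = int(k)
        out.append(
            make_trajectory(i, np.arange(k), np.zeros((k, 2)), dt=dt)
        )
    return out
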