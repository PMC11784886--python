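import numpy as np
import pytest

from diffuspect import Trajectory, build_reference_schedule


@pytest.fixture(scope="session")
def reference_schedule():
    return build_reference_schedule()


@pytest.fixture
def random_trajectory():
    """Small random (non-Brownian) trajectory for estimator checks."""
    rng = np.random.default_rng(1234)
    pos = rng.normal(size=(3, 50, 3))
    return Trajectory(np.arange(50) * 1e-9, pos)


def brute_force_msd(traj, max_lag=None):
    """Independent double-loop MSD oracle: averages the displacement
    products over every (origin, lag) pair and every particle."""
    n = traj.n_frames
    if max_lag is None:
        max_lag = n - 1
    pairs = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
    out = np.zeros((max_lag + 1, 6))
    pos = traj.positions
    for c, (a, b) in enumerate(pairs):
        for tau in range(max_lag + 1):
            acc = []
            for p in range(traj.n_particles):
                for t0 in range(n - tau):
                    da = pos[p, t0 + tau, a] - pos[p, t0, a]
                    db = pos[p, t0 + tau, b] - pos[p, t0, b]
                    acc.append(da * db)
            out[tau, c] = np.mean(acc)
    return out
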