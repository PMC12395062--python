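"""Shared fixtures: sensor grids, analytic beats, synthetic tables."""

import numpy as np
import pytest
from hypothesis import settings

from opmcg.containers import AveragedBeat, make_sensor_grid
from opmcg.simulate import (
    DipoleTrajectory,
    cardiac_trajectories,
    forward_bz_series,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return make_sensor_grid(4.0, 5.0)


@pytest.fixture(scope="session")
def static_dipole():
    """Factory: constant dipole trajectory at a given moment angle."""

    def make(angle_deg: float = 0.0, depth: float = 6.0,
             xy=(0.0, 0.0)) -> DipoleTrajectory:
        t = np.array([0.0, 1.0])
        m = np.array([np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))])
        return DipoleTrajectory(
            times=t,
            positions=np.array([[xy[0], xy[1], depth]] * 2),
            moments=np.array([m, m]),
        )

    return make


def make_noiseless_beat(grid, ischemia: float = 0.0, **kwargs) -> AveragedBeat:
    """Averaged beat rendered directly from the beat trajectories (no noise)."""
    trajs = cardiac_trajectories(ischemia_level=ischemia, **kwargs)
    t = trajs[0].times
    data = np.zeros((36, t.size))
    for traj in trajs:
        data += forward_bz_series(traj, grid, t)
    return AveragedBeat(data=data, fs=200.0, n_beats_used=100,
                        n_beats_rejected=0, offsets_ms=t)


@pytest.fixture(scope="session")
def noiseless_beat(grid):
    return make_noiseless_beat(grid, ischemia=0.0)


@pytest.fixture(scope="session")
def ischemic_beat(grid):
    return make_noiseless_beat(grid, ischemia=0.8)


@pytest.fixture(scope="session")
def feature_table():
    from opmcg.simulate import generate_feature_table

    return generate_feature_table(n=363, seed=1)


def true_r_samples(spec, seed: int) -> np.ndarray:
    """Ground-truth R-peak sample indices of `synthesize_recording`.

    Replays the generator's RR-jitter draws (the first uniforms of the
    seeded stream) to recover where beats were placed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.fs * spec.duration))
    rr_mean = 60.0 / spec.heart_rate * spec.fs
    r = 0.6 * spec.fs
    out = []
    while r < n:
        out.append(int(round(r)))
        r += rr_mean * (1.0 + rng.uniform(-0.03, 0.03))
    return np.array(out)
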