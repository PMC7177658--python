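import numpy as np
import pytest

from acrboost.trajectory_io import CarFollowingEpisode, TrajectoryRecord


def make_episode(v_l, v_f, a_f=None, d=None, dt=0.1, follower_id=1, leader_id=2):
    v_l = np.asarray(v_l, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    n = len(v_l)
    if a_f is None:
        a_f = np.gradient(v_f, dt)
    if d is None:
        d = np.full(n, 20.0)
    return CarFollowingEpisode(
        follower_id=follower_id,
        leader_id=leader_id,
        dt=dt,
        t=np.arange(n) * dt,
        v_l=v_l,
        v_f=v_f,
        a_f=np.asarray(a_f, dtype=float),
        d=np.asarray(d, dtype=float),
    )


def random_episode(rng, n=None):
    """A physically plausible random episode for fuzz tests."""
    n = n or int(rng.integers(20, 200))
    v_l = np.abs(rng.normal(8, 3, n))
    v_f = np.abs(v_l + rng.normal(0, 2, n))
    a_f = rng.normal(0, 1, n)
    d = np.abs(rng.normal(12, 6, n)) + 0.1
    return make_episode(v_l, v_f, a_f, d)


def follower_leader_records(
    n_frames,
    follower_id=10,
    leader_id=20,
    lane=1,
    start_frame=0,
    speed_f=10.0,
    speed_l=10.0,
    headway=20.0,
    leader_len=5.0,
):
    """Matched records for one leader-follower pair over n_frames."""
    recs = []
    for k in range(n_frames):
        f = start_frame + k
        recs.append(
            TrajectoryRecord(
                vehicle_id=follower_id,
                frame_index=f,
                lane_id=lane,
                preceding_id=leader_id,
                position=float(k) * speed_f * 0.1,
                speed=speed_f,
                acceleration=0.0,
                space_headway=headway,
                vehicle_length=4.0,
            )
        )
        recs.append(
            TrajectoryRecord(
                vehicle_id=leader_id,
                frame_index=f,
                lane_id=lane,
                preceding_id=0,
                position=float(k) * speed_l * 0.1 + headway,
                speed=speed_l,
                acceleration=0.0,
                space_headway=0.0,
                vehicle_length=leader_len,
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
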