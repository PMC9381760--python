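"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from groupinfluence import build_tables, simulate_group
from groupinfluence.io import RecordingSession, Trajectory
from groupinfluence.simulate import scenario_config

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


# ---------------------------------------------------------------- oracles

def haversine_m(lat1, lon1, lat2, lon2, radius=6_371_008.8):
    """Great-circle distance oracle, meters."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(a))


def brute_force_crossing(x, y, valid, t0, R, direction, use_path=False):
    """Exhaustive first-crossing scan: independent of the production kernels."""
    n = len(x)
    if direction == "future":
        js = range(t0 + 1, n)
    else:
        js = range(t0 - 1, -1, -1)
    acc = 0.0
    prev = t0
    for j in js:
        if not valid[j]:
            return -1
        if use_path:
            acc += float(np.hypot(x[j] - x[prev], y[j] - y[prev]))
            crossed = acc >= R
        else:
            crossed = float(np.hypot(x[j] - x[t0], y[j] - y[t0])) >= R
        if crossed:
            return j
        prev = j
    return -1


def stop_and_go_track(rng, n=400, p_move=0.7, noise=0.3):
    """Random track alternating digging pauses and bursts of travel."""
    heading = rng.uniform(0, 2 * np.pi)
    x, y = [0.0], [0.0]
    for _ in range(n - 1):
        if rng.random() < p_move:
            heading += rng.normal(0, 0.4)
            step = rng.exponential(0.4)
        else:
            step = 0.0
        x.append(x[-1] + step * np.cos(heading) + rng.normal(0, noise))
        y.append(y[-1] + step * np.sin(heading) + rng.normal(0, noise))
    valid = rng.random(n) > 0.05
    return np.array(x), np.array(y), valid


def make_session(x, y, valid=None, session_id="s0", group_id="g"):
    """Wrap (n_ind, T) arrays into a RecordingSession."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, T = x.shape
    if valid is None:
        valid = np.ones((n, T), dtype=bool)
    trs = [
        Trajectory(
            individual_id=f"m{i:02d}",
            status="unknown",
            t=np.arange(T, dtype=np.int64),
            x=x[i],
            y=y[i],
            valid=np.asarray(valid[i], bool),
        )
        for i in range(n)
    ]
    return RecordingSession(session_id, group_id, trs)


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def null_table():
    """Kinematic table of a two-session null-scenario cohort (R = 10 m)."""
    cfg = scenario_config("null", seed=101, n_sessions=2, duration=3600)
    sessions, _ = simulate_group(cfg)
    return build_tables(sessions, R=10.0)


@pytest.fixture(scope="session")
def leader_sessions():
    """Direction-leader cohort (agent m00 drives heading), three sessions."""
    cfg = scenario_config("direction_leader", seed=77, n_sessions=3, duration=1800)
    sessions, truth = simulate_group(cfg)
    return sessions, truth


@pytest.fixture(scope="session")
def leader_table(leader_sessions):
    sessions, _ = leader_sessions
    return build_tables(sessions, R=10.0)
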