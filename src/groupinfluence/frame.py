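"""Group reference frame and spatially-discretized kinematics.

At every second t and for every focal individual, the analysis asks: was the
focal moving toward the side the rest of the group subsequently turned to,
and was it moving faster than the rest of the group before the group sped
up? All velocities are spatially discretized: a velocity vector is the
displacement to the first fix at least R meters away divided by the time
taken, which suppresses GPS jitter and the stop-and-go cadence of foraging
movement. The group is represented by the leave-one-out centroid (the focal
is excluded from centroid location and movement, avoiding circularity); its
past velocity defines a front/right reference frame and the sign of
past x future determines the turn label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._scan import first_crossing_backward, first_crossing_forward
from .io import RecordingSession

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "session_id",
    "t",
    "focal_id",
    "lrm",
    "fb_speed_diff",
    "fb_position",
    "lr_position",
    "group_turn_right",
    "group_speed_up",
    "valid_turn",
    "valid_speed",
    "valid_position",
]


@dataclass
class DiscretizedVelocity:
    """Velocity from the first R-crossing of a track, anchored at t0."""

    t0: float
    vx: float
    vy: float
    span: float
    attained: bool

    @property
    def speed(self) -> float:
        return float(np.hypot(self.vx, self.vy))


@dataclass
class GroupFrame:
    """Front/right axes of the group at one time step.

    front is the unit vector of the centroid's past velocity; right is front
    rotated 90 degrees clockwise (x east, y north), so right = (front_y,
    -front_x).
    """

    t0: float
    front: np.ndarray
    right: np.ndarray
    centroid: np.ndarray


@dataclass
class KinematicTable:
    """Per-(time, focal) kinematic predictors and group outcome labels."""

    df: pd.DataFrame
    R: float
    group_id: str

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")

    @classmethod
    def concat(cls, tables: Sequence["KinematicTable"]) -> "KinematicTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        R = tables[0].R
        gid = tables[0].group_id
        if any(t.R != R for t in tables):
            raise ValueError("cannot concatenate tables with different R")
        df = pd.concat([t.df for t in tables], ignore_index=True)
        return cls(df=df, R=R, group_id=gid)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, R: float, group_id: str = "") -> "KinematicTable":
        return cls(df=pd.read_csv(path), R=R, group_id=group_id)


def _track_arrays(track) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if hasattr(track, "x"):
        return (
            np.ascontiguousarray(track.x, dtype=np.float64),
            np.ascontiguousarray(track.y, dtype=np.float64),
            np.ascontiguousarray(track.valid, dtype=np.bool_),
        )
    x, y = np.asarray(track[0], float), np.asarray(track[1], float)
    valid = (
        np.asarray(track[2], bool)
        if len(track) > 2
        else np.isfinite(x) & np.isfinite(y)
    )
    return (
        np.ascontiguousarray(x),
        np.ascontiguousarray(y),
        np.ascontiguousarray(valid),
    )


def discretized_velocity(
    track,
    t0: int,
    R: float,
    direction: str = "future",
    displacement_mode: str = "displacement",
) -> DiscretizedVelocity:
    """Spatially-discretized velocity of one track at time index t0.

    future: scan forward to the first valid fix whose straight-line
    displacement from position(t0) is >= R (or cumulative path length, with
    displacement_mode='path'); v = (pos(t1) - pos(t0)) / (t1 - t0).
    past: symmetric backward scan, v = (pos(t0) - pos(t1)) / (t0 - t1).
    The scan stops at the first invalid sample; if no crossing is reached the
    velocity is unattained and vx/vy are NaN.

    ``track`` may be a Trajectory or an (x, y[, valid]) tuple of arrays.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if direction not in ("past", "future"):
        raise ValueError("direction must be 'past' or 'future'")
    x, y, valid = _track_arrays(track)
    if not valid[t0]:
        raise ValueError(f"t0={t0} is not a valid sample")
    use_path = displacement_mode == "path"
    if direction == "future":
        idx = first_crossing_forward(x, y, valid, float(R), use_path)
        j = idx[t0]
        if j < 0:
            return DiscretizedVelocity(t0, np.nan, np.nan, np.nan, False)
        dt = float(j - t0)
        return DiscretizedVelocity(
            t0, (x[j] - x[t0]) / dt, (y[j] - y[t0]) / dt, dt, True
        )
    idx = first_crossing_backward(x, y, valid, float(R), use_path)
    j = idx[t0]
    if j < 0:
        return DiscretizedVelocity(t0, np.nan, np.nan, np.nan, False)
    dt = float(t0 - j)
    return DiscretizedVelocity(
        t0, (x[t0] - x[j]) / dt, (y[t0] - y[j]) / dt, dt, True
    )


def leave_one_out_centroid(
    session: RecordingSession, focal_id: Optional[str], t: int
) -> Optional[tuple[float, float]]:
    """Mean position of valid individuals at t, omitting ``focal_id``.

    With focal_id None this is the full-group centroid (used for front-back
    position and frontness). Returns None when no valid individual remains.
    """
    xs, ys = [], []
    for tr in session.trajectories:
        if tr.individual_id == focal_id or not tr.valid[t]:
            continue
        xs.append(tr.x[t])
        ys.append(tr.y[t])
    if not xs:
        return None
    return float(np.mean(xs)), float(np.mean(ys))


def reference_frame(
    centroid_past: DiscretizedVelocity, centroid_pos
) -> GroupFrame:
    """Group frame from the centroid's past velocity (front) at a position."""
    if not centroid_past.attained:
        raise ValueError("cannot build a frame from an unattained velocity")
    v = np.array([centroid_past.vx, centroid_past.vy], dtype=float)
    front = v / np.linalg.norm(v)
    right = np.array([front[1], -front[0]])
    return GroupFrame(
        t0=centroid_past.t0,
        front=front,
        right=right,
        centroid=np.asarray(centroid_pos, dtype=float),
    )


def label_group_motion(
    centroid_past: DiscretizedVelocity, centroid_future: DiscretizedVelocity
) -> tuple[Optional[int], Optional[int]]:
    """Group turn and speed-change labels from past vs. future velocity.

    turn_right = 1 when the future velocity lies clockwise of the past one
    (cross_z = past_x * future_y - past_y * future_x < 0), 0 when
    counterclockwise; speed_up = 1 when |v_future| > |v_past|. Exact ties and
    unattained velocities yield None (dropped, never assigned).
    """
    if not (centroid_past.attained and centroid_future.attained):
        return None, None
    cross = (
        centroid_past.vx * centroid_future.vy
        - centroid_past.vy * centroid_future.vx
    )
    turn = None if cross == 0 else int(cross < 0)
    sp, sf = centroid_past.speed, centroid_future.speed
    speed = None if sp == sf else int(sf > sp)
    return turn, speed


def individual_kinematics(
    focal_past: DiscretizedVelocity,
    focal_pos,
    frame: GroupFrame,
    centroid_past: DiscretizedVelocity,
) -> tuple[float, float, float]:
    """Focal predictors in the group frame.

    lrm: component of the focal's past velocity along the right axis
    (m/s, rightward positive). fb_speed_diff: focal's front-axis speed minus
    the group's past speed (m/s, positive when the focal outruns the group).
    fb_position: focal's position relative to the frame's centroid projected
    on the front axis (m, ahead positive).
    """
    u = np.array([focal_past.vx, focal_past.vy], dtype=float)
    lrm = float(u @ frame.right)
    fb_speed_diff = float(u @ frame.front) - centroid_past.speed
    rel = np.asarray(focal_pos, dtype=float) - frame.centroid
    fb_position = float(rel @ frame.front)
    return lrm, fb_speed_diff, fb_position


def _crossing_velocities(x, y, valid, R, use_path):
    """Vectorized past/future discretized velocities for a whole track.

    Returns dict with past/future component arrays and attained masks.
    """
    n = x.shape[0]
    fwd = first_crossing_forward(x, y, valid, R, use_path)
    bwd = first_crossing_backward(x, y, valid, R, use_path)
    t = np.arange(n)

    def vel(idx, sign):
        ok = idx >= 0
        j = np.where(ok, idx, 0)
        dt = np.where(ok, np.abs(t - j), 1).astype(float)
        vx = np.where(ok, sign * (x[j] - x[t]) / dt, np.nan)
        vy = np.where(ok, sign * (y[j] - y[t]) / dt, np.nan)
        return vx, vy, ok

    fvx, fvy, fok = vel(fwd, 1.0)
    pvx, pvy, pok = vel(bwd, -1.0)
    return {
        "future": (fvx, fvy, fok),
        "past": (pvx, pvy, pok),
    }


def build_kinematic_table(
    session: RecordingSession,
    R: float = 10.0,
    displacement_mode: str = "displacement",
) -> KinematicTable:
    """Full kinematic table of one preprocessed session.

    For each second and each focal: leave-one-out centroid track, its
    discretized past/future velocities and turn/speed labels, the focal's
    left-right movement and front-back speed difference in the leave-one-out
    frame, and the focal's front-back / left-right positions in the
    full-group centroid frame. Scans never bridge invalid samples (gaps,
    exclusion windows, session edges); validity flags record which
    components were attainable, and only rows with at least one valid
    component are emitted.
    """
    use_path = displacement_mode == "path"
    R = float(R)
    x, y, v = session.positions()
    n_ind, T = x.shape
    if n_ind < 2:
        logger.warning("session %s: fewer than 2 individuals", session.session_id)
        return KinematicTable(
            df=pd.DataFrame(columns=TABLE_COLUMNS), R=R, group_id=session.group_id
        )

    x0 = np.where(v, x, 0.0)
    y0 = np.where(v, y, 0.0)
    counts = v.sum(axis=0)

    # full-group centroid and frame (positional quantities)
    c_ok = counts >= 2
    denom = np.where(counts > 0, counts, 1)
    Cx = np.where(c_ok, x0.sum(axis=0) / denom, np.nan)
    Cy = np.where(c_ok, y0.sum(axis=0) / denom, np.nan)
    full = _crossing_velocities(
        np.ascontiguousarray(Cx), np.ascontiguousarray(Cy),
        np.ascontiguousarray(c_ok), R, use_path,
    )
    Fvx, Fvy, Fok = full["past"]
    Fn = np.hypot(Fvx, Fvy)
    with np.errstate(invalid="ignore"):
        Ffx, Ffy = Fvx / Fn, Fvy / Fn
    Frx, Fry = Ffy, -Ffx

    frames = []
    for f in range(n_ind):
        focal = session.trajectories[f]
        nb_counts = counts - v[f]
        l_ok = nb_counts >= 1
        nd = np.where(nb_counts > 0, nb_counts, 1)
        Lx = np.where(l_ok, (x0.sum(axis=0) - x0[f]) / nd, np.nan)
        Ly = np.where(l_ok, (y0.sum(axis=0) - y0[f]) / nd, np.nan)
        loo = _crossing_velocities(
            np.ascontiguousarray(Lx), np.ascontiguousarray(Ly),
            np.ascontiguousarray(l_ok), R, use_path,
        )
        pvx, pvy, pok = loo["past"]
        fvx, fvy, fok = loo["future"]

        with np.errstate(invalid="ignore"):
            cross = pvx * fvy - pvy * fvx
            sp = np.hypot(pvx, pvy)
            sf = np.hypot(fvx, fvy)
            turn = np.where(cross < 0, 1.0, np.where(cross > 0, 0.0, np.nan))
            speed = np.where(sf > sp, 1.0, np.where(sf < sp, 0.0, np.nan))
        lbl_ok = pok & fok
        turn = np.where(lbl_ok, turn, np.nan)
        speed = np.where(lbl_ok, speed, np.nan)

        # focal's own past velocity
        xf = np.ascontiguousarray(x[f])
        yf = np.ascontiguousarray(y[f])
        vf = np.ascontiguousarray(v[f])
        own = _crossing_velocities(xf, yf, vf, R, use_path)
        uvx, uvy, uok = own["past"]

        # leave-one-out frame
        with np.errstate(invalid="ignore"):
            ffx, ffy = pvx / sp, pvy / sp
            frx, fry = ffy, -ffx
            lrm = uvx * frx + uvy * fry
            fbs = uvx * ffx + uvy * ffy - sp
            fbp = (x[f] - Cx) * Ffx + (y[f] - Cy) * Ffy
            lrp = (x[f] - Cx) * Frx + (y[f] - Cy) * Fry

        valid_turn = lbl_ok & uok & pok & ~np.isnan(turn)
        valid_speed = lbl_ok & uok & pok & ~np.isnan(speed)
        valid_pos = Fok & v[f] & c_ok

        keep = valid_turn | valid_speed | valid_pos
        ts = np.flatnonzero(keep)
        if len(ts) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "session_id": session.session_id,
                    "t": ts,
                    "focal_id": focal.individual_id,
                    "lrm": np.where(uok & pok, lrm, np.nan)[ts],
                    "fb_speed_diff": np.where(uok & pok, fbs, np.nan)[ts],
                    "fb_position": np.where(valid_pos, fbp, np.nan)[ts],
                    "lr_position": np.where(valid_pos, lrp, np.nan)[ts],
                    "group_turn_right": turn[ts],
                    "group_speed_up": speed[ts],
                    "valid_turn": valid_turn[ts],
                    "valid_speed": valid_speed[ts],
                    "valid_position": valid_pos[ts],
                }
            )
        )
    if not frames:
        df = pd.DataFrame(columns=TABLE_COLUMNS)
    else:
        df = pd.concat(frames, ignore_index=True)
    return KinematicTable(df=df, R=R, group_id=session.group_id)


def build_tables(
    sessions: Iterable[RecordingSession],
    R: float = 10.0,
    displacement_mode: str = "displacement",
) -> KinematicTable:
    """Concatenated kinematic table over several sessions of one group."""
    tables = [
        build_kinematic_table(s, R=R, displacement_mode=displacement_mode)
        for s in sessions
    ]
    return KinematicTable.concat(tables)
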