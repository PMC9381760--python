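"""Reading, projecting, cleaning and segmenting multi-individual GPS tracks.

Raw input is a long-format CSV with one row per (session, individual, fix).
Positions may be geographic (lat/lon, projected here to a local planar frame)
or already planar (x_m/y_m, meters, x east / y north). Each recording session
is re-gridded to integer seconds from session start; every individual carries
a per-second validity mask so downstream velocity scans never bridge gaps,
disturbance windows, or samples outside the recorded span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Social status classes carried by collared individuals (juveniles are too
#: small to collar and therefore never appear in trajectory data).
STATUSES = (
    "dominant_female",
    "dominant_male",
    "adult",
    "yearling",
    "subadult",
    "unknown",
)

#: Mean Earth radius, meters (IUGG).
EARTH_RADIUS_M = 6_371_008.8


class ConfigurationError(ValueError):
    """Input file does not match the expected column layout."""


class DataError(ValueError):
    """Input rows violate a structural invariant (e.g. duplicate fixes)."""


@dataclass
class Trajectory:
    """One individual's track on the session's shared 1 Hz time base."""

    individual_id: str
    status: str
    t: np.ndarray          # int seconds since session start, 0..T-1
    x: np.ndarray          # meters east
    y: np.ndarray          # meters north
    valid: np.ndarray      # bool, per sample

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise DataError(
                f"unknown status {self.status!r} for {self.individual_id}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise DataError(
                f"non-monotonic time base for individual {self.individual_id}"
            )
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise DataError(
                f"non-finite valid position for individual {self.individual_id}"
            )

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class RecordingSession:
    """All simultaneously collared individuals of one group for one session."""

    session_id: str
    group_id: str
    trajectories: list[Trajectory]
    exclusion_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trajectories) < 2:
            raise DataError(
                f"session {self.session_id} needs >=2 individuals, "
                f"got {len(self.trajectories)}"
            )
        T = len(self.trajectories[0].t)
        for tr in self.trajectories:
            if len(tr.t) != T or tr.t[0] != 0:
                raise DataError(
                    f"session {self.session_id}: trajectories do not share "
                    "one time base"
                )

    @property
    def n_seconds(self) -> int:
        return len(self.trajectories[0].t)

    @property
    def individual_ids(self) -> list[str]:
        return [tr.individual_id for tr in self.trajectories]

    def positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack positions/validity as (n_ind, T) arrays for vector math."""
        x = np.stack([tr.x for tr in self.trajectories])
        y = np.stack([tr.y for tr in self.trajectories])
        v = np.stack([tr.valid for tr in self.trajectories])
        return x, y, v


def project_to_plane(lat, lon, origin: tuple[float, float]):
    """Project geographic coordinates to a local planar frame (meters).

    Spherical transverse Mercator centered on ``origin`` (lat0, lon0): the
    central meridian is mapped true to scale, x is east-positive, y
    north-positive and the origin maps to (0, 0). Scale distortion grows as
    (x / R_earth)^2 / 2 and is negligible (< 1e-4) within the few tens of
    kilometers the method is meant for.

    Parameters
    ----------
    lat, lon : array-like, degrees
    origin : (lat0, lon0) degrees

    Returns
    -------
    (x, y) : ndarrays, meters
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("latitude/longitude outside valid domain")
    lat0, lon0 = origin
    if abs(lat0) > 90.0 or abs(lon0) > 180.0:
        raise ValueError("origin outside valid domain")

    phi = np.radians(lat)
    dlam = np.radians(((lon - lon0) + 180.0) % 360.0 - 180.0)
    phi0 = np.radians(lat0)

    b = np.cos(phi) * np.sin(dlam)
    b = np.clip(b, -1.0 + 1e-15, 1.0 - 1e-15)
    x = EARTH_RADIUS_M * np.arctanh(b)
    y = EARTH_RADIUS_M * (np.arctan2(np.tan(phi), np.cos(dlam)) - phi0)
    return x, y


_DEFAULT_COLUMNS = {
    "session": "session_id",
    "id": "ind_id",
    "time": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "x": "x_m",
    "y": "y_m",
}


def _parse_times(col: pd.Series) -> np.ndarray:
    """Timestamps as float seconds (epoch or arbitrary zero)."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, utc=True, format="ISO8601")
    return parsed.astype("int64").to_numpy() / 1e9


def read_trajectories(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    meta: Optional[object] = None,
    exclusions: Optional[object] = None,
    group_id: Optional[str] = None,
) -> list[RecordingSession]:
    """Read a long-format tracks CSV into RecordingSessions.

    Parameters
    ----------
    path : str or file-like
        Tracks CSV. Mandatory columns (after ``column_map`` renaming):
        session_id, ind_id, timestamp, and either (lat, lon) or (x_m, y_m).
    column_map : mapping, optional
        Maps the roles 'session', 'id', 'time', 'lat', 'lon', 'x', 'y' to the
        actual column names in the file.
    meta : str/file-like or DataFrame, optional
        Table with columns ind_id, status. Individuals absent from it get
        status 'unknown'.
    exclusions : str/file-like or DataFrame, optional
        Table with columns session_id, start, end ([start, end) seconds from
        session start); attached to the sessions, applied by
        :func:`preprocess_sessions`.
    group_id : str, optional
        Group label; defaults to the session id prefix before the first '_',
        or the session id itself.

    Returns
    -------
    list of RecordingSession, ordered by session id; within each session
    trajectories are ordered by individual id and rows by time.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    for role in ("session", "id", "time"):
        if cols[role] not in df.columns:
            raise ConfigurationError(f"missing mandatory column {cols[role]!r}")
    planar = cols["x"] in df.columns and cols["y"] in df.columns
    geographic = cols["lat"] in df.columns and cols["lon"] in df.columns
    if not planar and not geographic:
        raise ConfigurationError(
            "need either planar (x_m, y_m) or geographic (lat, lon) columns"
        )

    status_of: dict[str, str] = {}
    if meta is not None:
        mdf = meta if isinstance(meta, pd.DataFrame) else pd.read_csv(meta)
        if not {"ind_id", "status"} <= set(mdf.columns):
            raise ConfigurationError("metadata needs columns ind_id, status")
        status_of = dict(zip(mdf["ind_id"].astype(str), mdf["status"]))

    excl_of: dict[str, list[tuple[float, float]]] = {}
    if exclusions is not None:
        edf = (
            exclusions
            if isinstance(exclusions, pd.DataFrame)
            else pd.read_csv(exclusions)
        )
        if not {"session_id", "start", "end"} <= set(edf.columns):
            raise ConfigurationError(
                "exclusions need columns session_id, start, end"
            )
        for _, row in edf.iterrows():
            excl_of.setdefault(str(row["session_id"]), []).append(
                (float(row["start"]), float(row["end"]))
            )

    df = df.copy()
    df["_t"] = _parse_times(df[cols["time"]])
    df = df.sort_values([cols["session"], cols["id"], "_t"], kind="mergesort")

    sessions = []
    for sid, sdf in df.groupby(cols["session"], sort=True):
        sid = str(sid)
        if geographic and not planar:
            origin = (
                float(sdf[cols["lat"]].median()),
                float(sdf[cols["lon"]].median()),
            )
            px, py = project_to_plane(
                sdf[cols["lat"]].to_numpy(), sdf[cols["lon"]].to_numpy(), origin
            )
        else:
            px = sdf[cols["x"]].to_numpy(dtype=float)
            py = sdf[cols["y"]].to_numpy(dtype=float)

        t0 = sdf["_t"].min()
        # snap to the session's integer-second grid
        tsec = np.rint(sdf["_t"].to_numpy() - t0).astype(np.int64)
        T = int(tsec.max()) + 1

        trajectories = []
        ids = sdf[cols["id"]].astype(str).to_numpy()
        for ind in sorted(set(ids)):
            m = ids == ind
            ts = tsec[m]
            if len(np.unique(ts)) != len(ts):
                raise DataError(
                    f"duplicate/colliding timestamps for individual {ind} "
                    f"in session {sid}"
                )
            x = np.full(T, np.nan)
            y = np.full(T, np.nan)
            valid = np.zeros(T, dtype=bool)
            x[ts] = px[m]
            y[ts] = py[m]
            valid[ts] = np.isfinite(px[m]) & np.isfinite(py[m])
            trajectories.append(
                Trajectory(
                    individual_id=ind,
                    status=status_of.get(ind, "unknown"),
                    t=np.arange(T, dtype=np.int64),
                    x=x,
                    y=y,
                    valid=valid,
                )
            )
        gid = group_id or (sid.split("_")[0] if "_" in sid else sid)
        sessions.append(
            RecordingSession(
                session_id=sid,
                group_id=gid,
                trajectories=trajectories,
                exclusion_intervals=excl_of.get(sid, []),
            )
        )
    return sessions


def _interpolate_gaps(
    tr: Trajectory, max_gap: float, never_fill: np.ndarray
) -> Trajectory:
    """Linearly fill interior invalid gaps of length <= max_gap seconds.

    Gaps touching a ``never_fill`` sample (exclusion windows) are left open so
    that repeated preprocessing is a no-op and no position is fabricated
    inside a disturbance. Invalid samples are normalized to NaN.
    """
    valid = tr.valid & ~never_fill
    x = np.where(valid, tr.x, np.nan)
    y = np.where(valid, tr.y, np.nan)
    idx = np.flatnonzero(valid)
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if gap == 0 or gap > max_gap or never_fill[a + 1 : b].any():
            continue
        ts = np.arange(a + 1, b)
        w = (ts - a) / (b - a)
        x[ts] = x[a] + w * (x[b] - x[a])
        y[ts] = y[a] + w * (y[b] - y[a])
        valid[ts] = True
    return replace(tr, x=x, y=y, valid=valid)


def preprocess_sessions(
    sessions: Iterable[RecordingSession],
    max_gap: float = 10.0,
    exclusions: Optional[Mapping[str, Sequence[tuple[float, float]]]] = None,
) -> list[RecordingSession]:
    """Interpolate short gaps and blank out disturbance windows.

    Gaps of at most ``max_gap`` seconds between two valid fixes are filled by
    linear interpolation and marked valid; longer gaps are left invalid.
    Nothing is fabricated before an individual's first or after its last fix.
    Every sample falling in an exclusion interval [start, end) — observer-noted
    disturbances such as predator alarms or inter-group encounters — is marked
    invalid for all individuals. Idempotent.

    Parameters
    ----------
    sessions : iterable of RecordingSession
    max_gap : float, seconds
    exclusions : mapping session_id -> [(start, end), ...], optional
        Merged with the intervals already attached to each session.
    """
    out = []
    for sess in sessions:
        intervals = list(sess.exclusion_intervals)
        if exclusions and sess.session_id in exclusions:
            intervals += [tuple(iv) for iv in exclusions[sess.session_id]]
        T = sess.n_seconds
        excl_mask = np.zeros(T, dtype=bool)
        for start, end in intervals:
            lo = max(int(np.ceil(start)), 0)
            hi = min(int(np.ceil(end)), T)
            excl_mask[lo:hi] = True

        new_trs = [
            _interpolate_gaps(tr, max_gap, excl_mask) for tr in sess.trajectories
        ]
        if all(tr.n_valid == 0 for tr in new_trs):
            logger.warning(
                "session %s has no valid samples after preprocessing",
                sess.session_id,
            )
        out.append(
            RecordingSession(
                session_id=sess.session_id,
                group_id=sess.group_id,
                trajectories=new_trs,
                exclusion_intervals=sorted(set(intervals)),
            )
        )
    return out
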