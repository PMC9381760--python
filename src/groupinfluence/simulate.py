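"""Agent-based simulator of cohesive stop-and-go foraging groups.

The latent group path is a correlated random walk: Poisson-timed turn events
(symmetric heading changes applied over ~20 s) and speed bursts that rise in
a few seconds and decay gradually, so speeding up is rarer than slowing
down. Agents forage around the path — an Ornstein-Uhlenbeck dispersion
offset, random digging pauses, and a bounded catch-up rule toward their
target point — emulating individuals that drift 1-10 m from their
neighbours while the group travels slowly and cohesively.

Influence ground truth is injected by temporal anticipation at the velocity
level, giving an unambiguous causal ordering: a direction driver moves along
a phase-advanced path that executes the group's heading changes ``lead_s``
seconds early (at the group's current speed), and a speed driver executes
the group's speed changes early (along the current heading); both stay
cohesive through a gentle tether to the latent path, and a coupling weight
in [0, 1] blends the anticipatory path with the ordinary one. Direction and
speed driving are independent knobs, so the two influence metrics can be
dissociated against known truth. Position-level (bounded target-shift)
injection does not work here: a bounded offset enters a chord-based
velocity as a time difference, whose trailing term anti-correlates with the
label's momentum and cancels the anticipatory signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import RecordingSession, Trajectory

SCENARIOS = (
    "null",
    "direction_leader",
    "speed_leader",
    "dual_leader",
    "front_biased",
)


@dataclass
class DriverSpec:
    """A designated influential agent: who, how strongly, how far ahead.

    The anticipation horizon ``lead_s`` defaults to about half the timescale
    over which the spatially-discretized velocities integrate movement
    (R / group speed ~ 35-40 s at R = 10 m): anticipation much shorter than
    the window is largely invisible to chord-based velocity estimates, while
    a much longer horizon mostly adds wander that is uncorrelated with the
    upcoming group motion.
    """

    agent: int
    coupling: float = 1.0
    lead_s: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if self.lead_s < 0:
            raise ValueError("lead_s must be >= 0")


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic cohesive group.

    Defaults describe slow, continuous foraging travel: ~0.2 m/s group
    speed, individuals dispersed a few meters around the centroid with
    frequent short digging pauses, occasional group reorientations, and
    asymmetric speed bursts (sharp rise, gradual decay).
    """

    n_individuals: int = 10
    duration: int = 10800          # seconds per session (3 h at 1 Hz)
    n_sessions: int = 1
    base_speed: float = 0.2        # m/s latent group travel speed
    cohesion_sd: float = 4.0       # m dispersion around the centroid
    pause_prob: float = 0.03       # per-second chance to start digging
    pause_mean_s: float = 8.0      # mean pause duration
    turn_rate: float = 0.5         # reorientation events per minute
    turn_sd_deg: float = 60.0      # sd of the heading change per event
    turn_dur_s: float = 20.0       # seconds over which a turn is executed
    heading_diffusion_deg: float = 3.0  # continuous heading wander, deg/sqrt(s)
    burst_rate: float = 0.5        # speed bursts per minute
    burst_gain: float = 1.5        # peak speed multiplier increment
    burst_rise_s: float = 5.0
    burst_decay_s: float = 40.0
    tether_tau_s: float = 60.0     # relaxation of a driver's advanced path
    v_max: float = 1.0             # m/s individual speed cap
    gps_noise_sd: float = 0.5      # m, iid position noise
    direction_driver: Optional[DriverSpec] = None
    speed_driver: Optional[DriverSpec] = None
    front_bias: Optional[tuple[int, float]] = None  # (agent, meters ahead)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "base_speed", "cohesion_sd", "pause_prob", "pause_mean_s",
            "turn_rate", "turn_sd_deg", "turn_dur_s", "burst_rate",
            "burst_gain", "burst_rise_s", "burst_decay_s", "gps_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for drv in (self.direction_driver, self.speed_driver):
            if drv is not None and not 0 <= drv.agent < self.n_individuals:
                raise ValueError("driver agent id out of range")
        if self.front_bias is not None:
            if not 0 <= self.front_bias[0] < self.n_individuals:
                raise ValueError("front-bias agent id out of range")


@dataclass
class GroundTruth:
    """True couplings and latent events behind a simulated cohort."""

    w_dir: np.ndarray
    w_spd: np.ndarray
    sessions: list = field(default_factory=list)  # per-session event dict

    @property
    def direction_driver(self) -> Optional[int]:
        return int(np.argmax(self.w_dir)) if self.w_dir.max() > 0 else None

    @property
    def speed_driver(self) -> Optional[int]:
        return int(np.argmax(self.w_spd)) if self.w_spd.max() > 0 else None


def _status_mock(n: int) -> list[str]:
    """Dominance-structure mock: one dominant pair, mixed subordinates."""
    cycle = ["adult", "yearling", "subadult"]
    out = []
    for i in range(n):
        if i == 0:
            out.append("dominant_female")
        elif i == 1:
            out.append("dominant_male")
        else:
            out.append(cycle[(i - 2) % 3])
    return out


def agent_ids(n: int) -> list[str]:
    return [f"m{i:02d}" for i in range(n)]


def _latent_path(cfg: SimulationConfig, rng: np.random.Generator, T_pad: int):
    """Heading, speed multiplier, and position of the latent group path."""
    dt = 1.0
    turn_p = cfg.turn_rate / 60.0 * dt
    burst_p = cfg.burst_rate / 60.0 * dt

    turn_times = np.flatnonzero(rng.random(T_pad) < turn_p)
    dtheta = rng.normal(0.0, np.radians(cfg.turn_sd_deg), size=len(turn_times))

    rate = np.zeros(T_pad)
    dur = max(int(round(cfg.turn_dur_s)), 1)
    for tau, dth in zip(turn_times, dtheta):
        hi = min(tau + dur, T_pad)
        rate[tau:hi] += dth / dur
    # continuous heading wander on top of discrete reorientation events: real
    # group paths are never piecewise straight, and persistent heading motion
    # is what the turn labels should reflect (rather than the mean-reverting
    # lateral meander of the centroid induced by cohesion noise)
    wander = rng.normal(0.0, np.radians(cfg.heading_diffusion_deg), size=T_pad)
    heading = rng.uniform(0, 2 * np.pi) + np.cumsum(rate + wander) * dt

    burst_times = np.flatnonzero(rng.random(T_pad) < burst_p)
    gains = cfg.burst_gain * rng.uniform(0.5, 1.5, size=len(burst_times))
    mult = np.ones(T_pad)
    rise = max(int(round(cfg.burst_rise_s)), 1)
    for tau, g in zip(burst_times, gains):
        prof = np.zeros(T_pad - tau)
        k = np.arange(T_pad - tau, dtype=float)
        up = k < rise
        prof[up] = g * (k[up] + 1) / rise
        prof[~up] = g * np.exp(-(k[~up] - rise + 1) / cfg.burst_decay_s)
        mult[tau:] += prof

    speed = cfg.base_speed * mult
    vx = speed * np.cos(heading)
    vy = speed * np.sin(heading)
    px = np.concatenate([[0.0], np.cumsum(vx)[:-1]])
    py = np.concatenate([[0.0], np.cumsum(vy)[:-1]])
    return {
        "heading": heading,
        "mult": mult,
        "px": px,
        "py": py,
        "turn_times": turn_times,
        "burst_times": burst_times,
    }


def _simulate_session(
    cfg: SimulationConfig, rng: np.random.Generator, session_id: str,
    group_id: str,
) -> tuple[RecordingSession, dict]:
    n = cfg.n_individuals
    T = int(cfg.duration)
    leads = [
        int(round(d.lead_s))
        for d in (cfg.direction_driver, cfg.speed_driver)
        if d is not None
    ]
    pad = (max(leads) if leads else 0) + int(cfg.turn_dur_s) + 2
    lat = _latent_path(cfg, rng, T + pad)
    hx, hy = np.cos(lat["heading"]), np.sin(lat["heading"])

    w_dir = np.zeros(n)
    w_spd = np.zeros(n)
    lead_dir = lead_spd = 0
    if cfg.direction_driver is not None:
        w_dir[cfg.direction_driver.agent] = cfg.direction_driver.coupling
        lead_dir = int(round(cfg.direction_driver.lead_s))
    if cfg.speed_driver is not None:
        w_spd[cfg.speed_driver.agent] = cfg.speed_driver.coupling
        lead_spd = int(round(cfg.speed_driver.lead_s))

    # Phase-advanced driver paths: the direction driver's path integrates the
    # group's *future* heading at its current speed; the speed driver's path
    # integrates the *future* speed along the current heading. A weak tether
    # (relaxation tether_tau_s, slower than the R-crossing window) keeps each
    # advanced path cohesive with the latent one without erasing the
    # anticipatory velocity signal from chord-based estimates.
    speed_now = cfg.base_speed * lat["mult"]
    kappa = 1.0 / max(cfg.tether_tau_s, 1.0)
    pdir = np.array([lat["px"][0], lat["py"][0]])
    pspd = pdir.copy()

    mu_front = np.zeros(n)
    if cfg.front_bias is not None:
        mu_front[cfg.front_bias[0]] = cfg.front_bias[1]

    # Agents track their target point without systematic lag: dispersion is a
    # world-frame OU offset around the latent path, movement is rate-limited
    # at v_max, and digging pauses freeze the agent briefly. Individual
    # deviations from the group are therefore uninformative about upcoming
    # group motion unless a driver's anticipatory target shift injects them.
    tau_off = 150.0
    off = rng.normal(0.0, cfg.cohesion_sd, size=(n, 2))
    eta_sd = cfg.cohesion_sd * np.sqrt(2.0 / tau_off)
    pos = np.stack([lat["px"][0] + off[:, 0], lat["py"][0] + off[:, 1]], axis=1)
    paused = np.zeros(n, dtype=bool)
    exit_p = 1.0 / max(cfg.pause_mean_s, 1.0)

    X = np.empty((n, T))
    Y = np.empty((n, T))
    for t in range(T):
        hvec = np.array([hx[t], hy[t]])
        mu = mu_front[:, None] * hvec[None, :]
        off += (mu - off) / tau_off + rng.normal(0.0, eta_sd, size=(n, 2))

        anchor = np.array([lat["px"][t], lat["py"][t]])
        target = anchor[None, :] + off
        if lead_dir:
            vd = speed_now[t] * np.array([hx[t + lead_dir], hy[t + lead_dir]])
            pdir = pdir + vd + kappa * (anchor - pdir)
            target += w_dir[:, None] * (pdir - anchor)[None, :]
        if lead_spd:
            vs = speed_now[t + lead_spd] * hvec
            pspd = pspd + vs + kappa * (anchor - pspd)
            target += w_spd[:, None] * (pspd - anchor)[None, :]

        u = rng.random(n)
        paused = np.where(paused, u >= exit_p, u < cfg.pause_prob)

        err = target - pos
        dist = np.hypot(err[:, 0], err[:, 1])
        step = np.minimum(dist, cfg.v_max)
        step = np.where(paused, 0.0, step)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[:, None] > 0, err / dist[:, None], 0.0)
        pos = pos + unit * step[:, None]
        X[:, t] = pos[:, 0]
        Y[:, t] = pos[:, 1]

    X += rng.normal(0.0, cfg.gps_noise_sd, size=X.shape)
    Y += rng.normal(0.0, cfg.gps_noise_sd, size=Y.shape)

    ids = agent_ids(n)
    statuses = _status_mock(n)
    trajectories = [
        Trajectory(
            individual_id=ids[i],
            status=statuses[i],
            t=np.arange(T, dtype=np.int64),
            x=X[i],
            y=Y[i],
            valid=np.ones(T, dtype=bool),
        )
        for i in range(n)
    ]
    session = RecordingSession(
        session_id=session_id, group_id=group_id, trajectories=trajectories
    )
    events = {
        "turn_times": lat["turn_times"][lat["turn_times"] < T].tolist(),
        "burst_times": lat["burst_times"][lat["burst_times"] < T].tolist(),
        "latent_x": lat["px"][:T],
        "latent_y": lat["py"][:T],
    }
    return session, events


def simulate_group(
    config: SimulationConfig,
) -> tuple[list[RecordingSession], GroundTruth]:
    """Simulate ``n_sessions`` recording sessions of one synthetic group.

    Fully reproducible from ``config.seed``: per-session generators are
    spawned from a single seed sequence, so output is byte-identical across
    runs.
    """
    n = config.n_individuals
    w_dir = np.zeros(n)
    w_spd = np.zeros(n)
    if config.direction_driver is not None:
        w_dir[config.direction_driver.agent] = config.direction_driver.coupling
    if config.speed_driver is not None:
        w_spd[config.speed_driver.agent] = config.speed_driver.coupling

    truth = GroundTruth(w_dir=w_dir, w_spd=w_spd)
    sessions = []
    for s in range(config.n_sessions):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(s,))
        )
        sess, events = _simulate_session(
            config, rng, session_id=f"sim_{s:02d}", group_id="sim"
        )
        sessions.append(sess)
        truth.sessions.append(events)
    return sessions, truth


def scenario_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Reference configuration of a named scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    kw: dict = dict(
        n_individuals=10, duration=3600, n_sessions=3, seed=seed
    )
    if name == "direction_leader":
        kw["direction_driver"] = DriverSpec(agent=0, coupling=1.0)
    elif name == "speed_leader":
        kw["speed_driver"] = DriverSpec(agent=0, coupling=1.0)
    elif name == "dual_leader":
        kw["direction_driver"] = DriverSpec(agent=0, coupling=1.0)
        kw["speed_driver"] = DriverSpec(agent=1, coupling=1.0)
    elif name == "front_biased":
        kw["front_bias"] = (0, 8.0)
    kw.update(overrides)
    return SimulationConfig(**kw)


def sessions_to_frame(sessions: list[RecordingSession]) -> pd.DataFrame:
    """Long-format tracks table in the CSV dialect the reader accepts."""
    parts = []
    for sess in sessions:
        for tr in sess.trajectories:
            m = tr.valid
            parts.append(
                pd.DataFrame(
                    {
                        "session_id": sess.session_id,
                        "ind_id": tr.individual_id,
                        "timestamp": tr.t[m],
                        "x_m": tr.x[m],
                        "y_m": tr.y[m],
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def generate_scenario(name: str, seed: int, out_dir, **overrides) -> dict:
    """Write a scenario's tracks/meta/exclusions CSVs and ground truth.

    Files: tracks.csv, meta.csv, exclusions.csv (empty), ground_truth.json
    (couplings, driver ids, event times, generating parameters). Returns the
    paths. ``overrides`` adjust the reference configuration (e.g. a shorter
    duration for quick runs).
    """
    cfg = scenario_config(name, seed=seed, **overrides)
    sessions, truth = simulate_group(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tracks = out / "tracks.csv"
    sessions_to_frame(sessions).to_csv(tracks, index=False)

    meta = out / "meta.csv"
    pd.DataFrame(
        {
            "ind_id": agent_ids(cfg.n_individuals),
            "status": _status_mock(cfg.n_individuals),
        }
    ).to_csv(meta, index=False)

    excl = out / "exclusions.csv"
    pd.DataFrame(columns=["session_id", "start", "end", "label"]).to_csv(
        excl, index=False
    )

    gt_path = out / "ground_truth.json"
    ids = agent_ids(cfg.n_individuals)
    cfg_dict = asdict(cfg)
    gt = {
        "scenario": name,
        "seed": seed,
        "w_dir": dict(zip(ids, truth.w_dir.tolist())),
        "w_spd": dict(zip(ids, truth.w_spd.tolist())),
        "direction_driver": (
            ids[truth.direction_driver]
            if truth.direction_driver is not None
            else None
        ),
        "speed_driver": (
            ids[truth.speed_driver] if truth.speed_driver is not None else None
        ),
        "events": [
            {k: s[k] for k in ("turn_times", "burst_times")}
            for s in truth.sessions
        ],
        "config": cfg_dict,
    }
    with open(gt_path, "w") as fh:
        json.dump(gt, fh, indent=1)
    return {
        "tracks": str(tracks),
        "meta": str(meta),
        "exclusions": str(excl),
        "ground_truth": str(gt_path),
    }
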