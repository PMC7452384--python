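"""Synthetic coupled swimmers, relay-channel replicas, and symbol chains.

Everything the analysis chain consumes can be generated here with known
ground truth:

* :func:`simulate_dyad` — two subjects in a bounded rectangular arena.  The
  leader swims with a mean-reverting (Ornstein-Uhlenbeck) speed and an
  autocorrelated heading with soft wall avoidance.  The follower blends its
  own identical dynamics with the leader's *lagged* speed and heading with
  weight ``c`` (the coupling strength) at lag ``tau``, plus a
  distance-dependent attraction toward the leader.  Coupling acts on the
  velocity channels — speed and heading — precisely the channels the
  analysis reads, so leader-follower structure is recoverable by transfer
  entropy and lagged cross-correlation.

* :func:`teleport_channel` — a noisy delayed relay: the replica trajectory
  is the input delayed by ``delay`` (plus per-frame timing jitter), with
  additive positional noise, and a fraction of frames dropped (marked
  missing), emulating an imperfect real-time mirroring channel.

* :func:`simulate_coupled_chain` — a symbol-level oracle with an analytic
  transfer entropy: X is i.i.d. uniform over the 4 symbols and
  ``Y[t+1] = X[t]`` with probability ``c``, else uniform.  Its exact
  TE is available in closed form (:func:`coupled_chain_te`), which makes it
  the calibration standard for the plug-in estimator.

All generators are bit-reproducible given their configuration and seed.
Defaults mirror the study design the analysis is meant for: 10-minute
sessions at 30 Hz, 12 pairs per condition, a small leader paired with a
large follower (~33% body-size difference, metadata only).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .kinematics import Condition, SizeClass, Trajectory, wrap_angle
from .symbolize import ALPHABET_SIZE, SymbolSeries

__all__ = [
    "DyadSimConfig",
    "ChannelConfig",
    "simulate_dyad",
    "teleport_channel",
    "simulate_coupled_chain",
    "coupled_chain_te",
]


@dataclass
class DyadSimConfig:
    """Parameters of the coupled-swimmer generator.

    Units: lengths in centimetres, times in seconds, angles in radians.
    Speed follows an Ornstein-Uhlenbeck process (mean ``speed_mean``,
    reversion rate ``speed_reversion`` per second, diffusion
    ``speed_noise_sd`` per sqrt-second); heading diffuses with standard
    deviation ``heading_noise_sd`` per sqrt-second plus a wall-avoidance
    steer of gain ``wall_gain`` active within ``wall_margin`` of a wall.

    ``coupling_strength`` in [0, 1] is the per-frame weight with which the
    follower's speed and heading are pulled toward the leader's values
    ``coupling_lag`` seconds earlier; ``attraction_gain`` steers the
    follower toward the leader's lagged position (shoaling).  Setting both
    to 0 yields two statistically independent swimmers.
    """

    duration: float = 600.0        # seconds; one 10-min session
    frame_rate: float = 30.0       # Hz
    arena: tuple[float, float] = (90.0, 90.0)   # cm (width, height)
    leader: SizeClass = SizeClass.SMALL
    coupling_strength: float = 0.6
    coupling_lag: float = 0.1      # seconds
    speed_mean: float = 8.0        # cm/s, ~2.5 body lengths/s for a small adult
    speed_reversion: float = 1.5   # 1/s
    speed_noise_sd: float = 6.0    # cm/s per sqrt(s)
    heading_noise_sd: float = 1.8  # rad per sqrt(s)
    wall_margin: float = 12.0      # cm
    wall_gain: float = 4.0         # 1/s
    attraction_gain: float = 0.8   # 1/s
    body_length_small: float = 3.0  # cm (metadata)
    body_length_large: float = 4.0  # cm, ~33% larger (metadata)
    condition: Condition = Condition.CONTROL
    pair_id: str = "pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.coupling_lag < 0:
            raise ValueError("coupling_lag must be >= 0")
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        # a swimmer must be able to turn away before crossing the arena
        if self.speed_mean / self.frame_rate > min(self.arena) / 2:
            raise ValueError("infeasible config: arena too small for speeds")
        self.leader = SizeClass(self.leader)
        self.condition = Condition(self.condition)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["leader"] = self.leader.value
        d["condition"] = self.condition.value
        return d


@dataclass
class ChannelConfig:
    """Noisy delayed relay channel producing a replica trajectory."""

    delay: float = 0.1            # seconds
    jitter_sd: float = 0.0        # seconds, per-frame timing jitter
    dropout_fraction: float = 0.0  # fraction of frames lost
    position_noise_sd: float = 0.0  # length units

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _simulate_swimmer(
    n: int,
    dt: float,
    cfg: DyadSimConfig,
    rng: np.random.Generator,
    leader_speed: np.ndarray | None = None,
    leader_heading: np.ndarray | None = None,
    leader_pos: np.ndarray | None = None,
    lag_frames: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One swimmer; optionally coupled to a pre-computed leader.

    Returns (x, y) arrays of length n.  Noise draws are made in a fixed
    order so the output is bit-reproducible for a given generator state.
    """
    w, h = cfg.arena
    cx, cy = w / 2.0, h / 2.0
    c = cfg.coupling_strength if leader_speed is not None else 0.0
    sqdt = np.sqrt(dt)

    speed_noise = rng.normal(0.0, cfg.speed_noise_sd * sqdt, size=n)
    head_noise = rng.normal(0.0, cfg.heading_noise_sd * sqdt, size=n)
    x = np.empty(n)
    y = np.empty(n)
    x[0] = cx + rng.uniform(-0.25, 0.25) * w
    y[0] = cy + rng.uniform(-0.25, 0.25) * h
    s = max(0.0, cfg.speed_mean + rng.normal(0.0, 1.0))
    th = rng.uniform(-np.pi, np.pi)

    for i in range(1, n):
        # own dynamics: OU speed, diffusing heading, wall avoidance
        s = s + cfg.speed_reversion * (cfg.speed_mean - s) * dt + speed_noise[i]
        th = th + head_noise[i]
        dist_wall = min(x[i - 1], w - x[i - 1], y[i - 1], h - y[i - 1])
        if dist_wall < cfg.wall_margin:
            bearing = np.arctan2(cy - y[i - 1], cx - x[i - 1])
            th = th + cfg.wall_gain * dt * wrap_angle(bearing - th)
        if c > 0.0:
            j = i - 1 - lag_frames
            if j >= 0:
                # blend toward the leader's lagged speed and heading
                s = (1.0 - c) * s + c * leader_speed[j]
                th = th + c * wrap_angle(leader_heading[j] - th)
        if cfg.attraction_gain > 0.0 and leader_pos is not None:
            j = max(0, i - 1 - lag_frames)
            bearing = np.arctan2(leader_pos[j, 1] - y[i - 1], leader_pos[j, 0] - x[i - 1])
            d = np.hypot(leader_pos[j, 0] - x[i - 1], leader_pos[j, 1] - y[i - 1])
            # saturating attraction: full gain beyond ~2 body lengths
            strength = cfg.attraction_gain * dt * min(1.0, d / (2.0 * cfg.body_length_small))
            th = th + strength * wrap_angle(bearing - th)
        s = max(0.0, s)
        xi = x[i - 1] + s * np.cos(th) * dt
        yi = y[i - 1] + s * np.sin(th) * dt
        # reflect at the walls, flipping the corresponding velocity component
        if xi < 0.0:
            xi = -xi
            th = wrap_angle(np.pi - th)
        elif xi > w:
            xi = 2.0 * w - xi
            th = wrap_angle(np.pi - th)
        if yi < 0.0:
            yi = -yi
            th = -th
        elif yi > h:
            yi = 2.0 * h - yi
            th = -th
        x[i], y[i] = xi, yi
    return x, y


def _speed_heading(x: np.ndarray, y: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    sp = np.hypot(np.diff(x), np.diff(y)) / dt
    th = np.arctan2(np.diff(y), np.diff(x))
    # pad to length n so lagged indexing stays simple
    return np.r_[sp, sp[-1]], np.r_[th, th[-1]]


def simulate_dyad(cfg: DyadSimConfig) -> tuple[Trajectory, Trajectory]:
    """Simulate one coupled dyad; returns ``(small, large)`` trajectories.

    The configured leader is simulated first from its own noise stream; the
    follower is then simulated from an independent stream, blending toward
    the leader's realized (lagged) speed and heading with weight
    ``coupling_strength`` and steering toward its lagged position with
    ``attraction_gain``.  Separate child streams per subject keep the
    leader's path unchanged when only follower parameters vary.
    """
    dt = 1.0 / cfg.frame_rate
    n = int(round(cfg.duration * cfg.frame_rate))
    if n < 3:
        raise ValueError("insufficient duration")
    lag_frames = int(round(cfg.coupling_lag * cfg.frame_rate))
    ss = np.random.SeedSequence(cfg.seed)
    rng_leader, rng_follower = (np.random.default_rng(s) for s in ss.spawn(2))

    lx, ly = _simulate_swimmer(n, dt, cfg, rng_leader)
    l_speed, l_head = _speed_heading(lx, ly, dt)
    l_pos = np.column_stack([lx, ly])
    fx, fy = _simulate_swimmer(
        n, dt, cfg, rng_follower,
        leader_speed=l_speed, leader_heading=l_head,
        leader_pos=l_pos if cfg.attraction_gain > 0 else None,
        lag_frames=lag_frames,
    )

    t = np.arange(n) * dt
    bounds = (0.0, cfg.arena[0], 0.0, cfg.arena[1])

    def _traj(x: np.ndarray, y: np.ndarray, size: SizeClass) -> Trajectory:
        return Trajectory(
            t=t, x=x, y=y, frame_rate=cfg.frame_rate, arena_bounds=bounds,
            subject_id=f"{cfg.pair_id}-{size.value}",
            size_class=size, condition=cfg.condition,
        )

    if cfg.leader == SizeClass.SMALL:
        return _traj(lx, ly, SizeClass.SMALL), _traj(fx, fy, SizeClass.LARGE)
    return _traj(fx, fy, SizeClass.SMALL), _traj(lx, ly, SizeClass.LARGE)


def teleport_channel(
    traj: Trajectory,
    ch: ChannelConfig,
    rng: np.random.Generator | int | None = 0,
) -> Trajectory:
    """Pass a trajectory through a noisy delayed relay; returns the replica.

    The replica samples the input ``delay`` (+/- per-frame jitter) seconds
    in the past, with additive Gaussian positional noise; a
    ``dropout_fraction`` of frames is marked missing (NaN).  Frames whose
    delayed lookup time precedes the session start are also missing.
    Deterministic given the rng seed; the channel uses its own stream so it
    can be toggled without altering the underlying dyad.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = traj.t
    shift = ch.delay + (
        rng.normal(0.0, ch.jitter_sd, size=len(t)) if ch.jitter_sd > 0 else 0.0
    )
    t_src = t - np.maximum(shift, 0.0)
    ok = np.isfinite(traj.x) & np.isfinite(traj.y)
    x = np.interp(t_src, t[ok], traj.x[ok], left=np.nan)
    y = np.interp(t_src, t[ok], traj.y[ok], left=np.nan)
    if ch.position_noise_sd > 0:
        x = x + rng.normal(0.0, ch.position_noise_sd, size=len(t))
        y = y + rng.normal(0.0, ch.position_noise_sd, size=len(t))
    if ch.dropout_fraction > 0:
        lost = rng.random(len(t)) < ch.dropout_fraction
        x[lost] = np.nan
        y[lost] = np.nan
    xmin, xmax, ymin, ymax = traj.arena_bounds
    x = np.clip(x, xmin, xmax)
    y = np.clip(y, ymin, ymax)
    return Trajectory(
        t=t, x=x, y=y, frame_rate=traj.frame_rate,
        arena_bounds=traj.arena_bounds,
        subject_id=f"{traj.subject_id}-replica",
        size_class=traj.size_class, condition=traj.condition,
    )


def simulate_coupled_chain(
    c: float,
    n: int,
    rng: np.random.Generator | int | None = 0,
) -> tuple[SymbolSeries, SymbolSeries]:
    """Coupled 4-symbol Markov chain with analytically known TE.

    ``X`` is i.i.d. uniform over the alphabet; ``Y[t+1] = X[t]`` with
    probability ``c`` and i.i.d. uniform otherwise, so the only information
    channel is X's one-step-lagged influence on Y.  The exact
    TE from X to Y is :func:`coupled_chain_te`(c): 0 bits at c=0, 2 bits at
    c=1.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("coupling c must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = rng.integers(0, ALPHABET_SIZE, size=n)
    fresh = rng.integers(0, ALPHABET_SIZE, size=n)
    copy = rng.random(n) < c
    y = np.empty(n, dtype=np.int64)
    y[0] = fresh[0]
    y[1:] = np.where(copy[1:], x[:-1], fresh[1:])
    t = np.arange(n, dtype=float)
    return (
        SymbolSeries(t=t, codes=x, subject_id="X", frame_rate=1.0),
        SymbolSeries(t=t, codes=y, subject_id="Y", frame_rate=1.0),
    )


def coupled_chain_te(c: float, base: float = 2.0) -> float:
    """Exact transfer entropy of the coupled chain, in units of ``base``.

    Y[t+1] equals X[t] with probability c, else uniform; Y[t+1] is
    independent of Y[t], so TE = H(Y[t+1]) - H(Y[t+1] | X[t]).  Given
    X[t], Y[t+1] takes the copied value with probability
    ``p = c + (1 - c)/4`` and each other value with ``q = (1 - c)/4``:

        TE = log(4) + p log p + 3 q log q
    """
    m = ALPHABET_SIZE
    p = c + (1.0 - c) / m
    q = (1.0 - c) / m
    h = -(p * np.log(p) if p > 0 else 0.0) - (m - 1) * (q * np.log(q) if q > 0 else 0.0)
    return float((np.log(m) - h) / np.log(base))
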