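"""Trajectory containers and trajectory-to-kinematics conversion.

Raw input is a planar trajectory: per-frame timestamps and (x, y) positions
of one subject in a bounded rectangular arena.  Everything downstream
(symbolization, transfer entropy, cross-correlation) operates on the derived
kinematic series: speed, turn rate, and their discrete time derivatives
(linear and angular acceleration).

Conventions
-----------
* Speed is the forward finite difference of position: the velocity that
  lives between frames ``i`` and ``i+1`` is assigned to time ``t_i``.
* Heading is ``atan2(dy, dx)`` of the same displacement.
* Turn rate is, by default, the UNSIGNED angular speed: the magnitude of the
  wrapped heading change per unit time.  This makes "increase in turn rate"
  well defined irrespective of turning direction; a signed variant is
  available via ``signed_turn_rate=True``.
* Accelerations are centred differences in the interior and one-sided at the
  ends, so that the two acceleration series being jointly symbolized carry
  no relative phase shift.
* Missing samples are encoded as NaN positions; :func:`fill_gaps` linearly
  interpolates short dropouts and splits the session at long ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "SizeClass",
    "Condition",
    "Trajectory",
    "KinematicSeries",
    "compute_kinematics",
    "fill_gaps",
    "headings",
    "wrap_angle",
]


class SizeClass(str, Enum):
    SMALL = "small"
    LARGE = "large"


class Condition(str, Enum):
    CONTROL = "control"
    MATCH = "match"
    MISMATCH = "mismatch"


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-pi, pi]."""
    wrapped = -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


@dataclass
class Trajectory:
    """Timestamped planar positions of one subject in one session.

    Positions may contain NaN for tracking dropouts; ``t`` must be strictly
    increasing.  ``arena_bounds`` is ``(xmin, xmax, ymin, ymax)`` in the same
    length units as ``x`` and ``y``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    arena_bounds: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)
    subject_id: str = "subject"
    size_class: SizeClass = SizeClass.SMALL
    condition: Condition = Condition.CONTROL
    # segment start indices produced by gap splitting; a single segment by default
    segment_starts: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 3:
            raise ValueError("insufficient data: need at least 3 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("invalid time base: timestamps must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.size_class = SizeClass(self.size_class)
        self.condition = Condition(self.condition)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.x) & np.isfinite(self.y)))

    def segments(self) -> list[slice]:
        """Slices of the independently analyzable segments."""
        starts = list(self.segment_starts) + [len(self.t)]
        return [slice(a, b) for a, b in zip(starts[:-1], starts[1:]) if b - a > 0]


@dataclass
class KinematicSeries:
    """Speed, turn-rate and acceleration series sharing one time base.

    ``speed`` (length-units/s) and ``turn_rate`` (rad/s, unsigned by default)
    are non-negative; ``lin_accel`` and ``ang_accel`` are their signed
    discrete derivatives on the same clock.
    """

    t: np.ndarray
    speed: np.ndarray
    turn_rate: np.ndarray
    lin_accel: np.ndarray
    ang_accel: np.ndarray
    frame_rate: float = 0.0
    subject_id: str = "subject"
    segment_starts: tuple[int, ...] = (0,)

    def __len__(self) -> int:
        return len(self.t)

    def segments(self) -> list[slice]:
        starts = list(self.segment_starts) + [len(self.t)]
        return [slice(a, b) for a, b in zip(starts[:-1], starts[1:]) if b - a > 0]


def headings(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-step heading angle of the displacement vectors (length n-1).

    Heading is undefined while stationary; zero-displacement steps carry the
    last defined heading so the result is invariant under rigid rotation of
    the arena frame.
    """
    dx, dy = np.diff(x), np.diff(y)
    head = np.arctan2(dy, dx)
    moving = (dx != 0.0) | (dy != 0.0)
    if not moving.all():
        if moving.any():
            idx = np.where(moving, np.arange(len(head)), -1)
            idx = np.maximum.accumulate(idx)
            idx[idx < 0] = np.argmax(moving)
            head = head[idx]
        else:
            head = np.zeros_like(head)
    return head


def _moving_average(v: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return v
    kernel = np.ones(win) / win
    # reflect-pad so the ends are averaged over a full window
    pad = win // 2
    vp = np.pad(v, pad, mode="edge")
    out = np.convolve(vp, kernel, mode="same")[pad : pad + len(v)]
    return out


def _derivative(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Centred differences in the interior, one-sided at the ends."""
    return np.gradient(v, t)


def _kinematics_of_segment(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    smooth_n: int,
    signed_turn_rate: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    dt = np.diff(t)
    speed = np.hypot(np.diff(x), np.diff(y)) / dt          # n-1, at t[:-1]
    head = headings(x, y)                                  # n-1
    dhead = wrap_angle(np.diff(head))                      # n-2
    turn = dhead / dt[:-1]
    if not signed_turn_rate:
        turn = np.abs(turn)
    # common clock: first n-2 samples
    m = len(t) - 2
    tt = t[:m]
    sp = _moving_average(speed[:m], smooth_n)
    tr = _moving_average(turn[:m], smooth_n)
    if m >= 2:
        la = _derivative(sp, tt)
        aa = _derivative(tr, tt)
    else:
        la = np.zeros(m)
        aa = np.zeros(m)
    return tt, sp, tr, la, aa


def compute_kinematics(
    traj: Trajectory,
    smooth_window: float = 0.1,
    signed_turn_rate: bool = False,
) -> KinematicSeries:
    """Derive speed, turn rate and accelerations from a trajectory.

    Parameters
    ----------
    traj
        Input trajectory.  NaN positions must have been handled by
        :func:`fill_gaps` first; segments are processed independently and
        concatenated (their boundaries are carried through so that joint
        counts are never bridged across a gap).
    smooth_window
        Moving-average window in seconds applied to speed and turn rate
        before differentiation (suppresses pixel-quantization jitter).
        0 disables smoothing.  The default of 0.1 s is ~3 samples at 30 Hz.
    signed_turn_rate
        If True, keep the sign of the heading change (positive =
        counter-clockwise); the default is unsigned angular speed.
    """
    if smooth_window < 0:
        raise ValueError("smooth_window must be >= 0")
    out_t, out_sp, out_tr, out_la, out_aa = [], [], [], [], []
    seg_starts = [0]
    for seg in traj.segments():
        t, x, y = traj.t[seg], traj.x[seg], traj.y[seg]
        ok = np.isfinite(x) & np.isfinite(y)
        t, x, y = t[ok], x[ok], y[ok]
        if len(t) < 3:
            continue
        smooth_n = max(1, int(round(smooth_window * traj.frame_rate)))
        tt, sp, tr, la, aa = _kinematics_of_segment(t, x, y, smooth_n, signed_turn_rate)
        out_t.append(tt)
        out_sp.append(sp)
        out_tr.append(tr)
        out_la.append(la)
        out_aa.append(aa)
        seg_starts.append(seg_starts[-1] + len(tt))
    if not out_t:
        raise ValueError("insufficient data: no segment has >= 3 valid samples")
    return KinematicSeries(
        t=np.concatenate(out_t),
        speed=np.concatenate(out_sp),
        turn_rate=np.concatenate(out_tr),
        lin_accel=np.concatenate(out_la),
        ang_accel=np.concatenate(out_aa),
        frame_rate=traj.frame_rate,
        subject_id=traj.subject_id,
        segment_starts=tuple(seg_starts[:-1]),
    )


def fill_gaps(traj: Trajectory, max_gap: float = 0.5) -> Trajectory:
    """Interpolate short tracking dropouts; split the session at long ones.

    Runs of NaN positions spanning at most ``max_gap`` seconds are linearly
    interpolated in x and y.  Longer runs split the trajectory into segments
    that downstream statistics treat independently (no statistic is ever
    computed across a split).  Returns a new Trajectory whose
    ``segment_starts`` record the split points; remaining NaN samples inside
    long gaps are dropped.
    """
    x = traj.x.copy()
    y = traj.y.copy()
    t = traj.t
    missing = ~(np.isfinite(x) & np.isfinite(y))
    if missing.all():
        raise ValueError("empty trajectory: all samples missing")
    if not missing.any():
        return replace(traj, segment_starts=(0,))

    # identify runs of missing samples
    idx = np.flatnonzero(missing)
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]  # inclusive

    keep = np.ones(len(t), dtype=bool)
    split_after: list[int] = []  # indices (into kept arrays) where a new segment starts
    for a, b in zip(run_starts, run_ends):
        lo, hi = a - 1, b + 1  # flanking valid samples (may be out of range)
        gap_span = (t[min(hi, len(t) - 1)] - t[max(lo, 0)])
        if lo < 0 or hi >= len(t) or gap_span > max_gap:
            keep[a : b + 1] = False
            split_after.append(b)
        else:
            frac = (t[a : b + 1] - t[lo]) / (t[hi] - t[lo])
            x[a : b + 1] = x[lo] + frac * (x[hi] - x[lo])
            y[a : b + 1] = y[lo] + frac * (y[hi] - y[lo])

    new_index = np.cumsum(keep) - 1  # original index -> kept index
    starts = {0}
    for b in split_after:
        nxt = b + 1
        if nxt < len(t) and keep[nxt]:
            starts.add(int(new_index[nxt]))
    t2, x2, y2 = t[keep], x[keep], y[keep]
    if len(t2) < 3:
        raise ValueError("insufficient data after gap handling")
    return replace(
        traj,
        t=t2,
        x=x2,
        y=y2,
        segment_starts=tuple(sorted(s for s in starts if s < len(t2))),
    )
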