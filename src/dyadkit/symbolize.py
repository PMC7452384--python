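"""Joint symbolization of speed and turn-rate dynamics.

Each frame is encoded by one of four symbols built from the signs of the
linear and the angular acceleration: the first letter is "-" when speed is
decreasing and "+" when increasing, the second letter likewise for turn
rate.  The alphabet is therefore {"--", "-+", "+-", "++"}, stored internally
as integer codes 0..3 (first letter is the high bit).

Exact zero accelerations carry no sign; by default a plateau continues the
preceding trend in that channel (deterministic carry-last rule, each channel
handled independently, initialized to "-").  A seeded random-sign rule is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicSeries

__all__ = ["SymbolSeries", "symbolize", "ALPHABET", "ALPHABET_SIZE", "symbol_labels"]

ALPHABET = ("--", "-+", "+-", "++")
ALPHABET_SIZE = 4


@dataclass
class SymbolSeries:
    """A 4-letter joint symbol sequence with its time base.

    ``codes`` holds integers in {0, 1, 2, 3} mapping to
    ``("--", "-+", "+-", "++")``: code = 2 * (speed increasing) +
    (turn rate increasing).
    """

    t: np.ndarray
    codes: np.ndarray
    frame_rate: float = 0.0
    subject_id: str = "subject"
    segment_starts: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if len(self.codes) and (self.codes.min() < 0 or self.codes.max() >= ALPHABET_SIZE):
            raise ValueError("symbol codes must lie in 0..3")

    def __len__(self) -> int:
        return len(self.codes)

    def labels(self) -> list[str]:
        return [ALPHABET[c] for c in self.codes]

    def segments(self) -> list[np.ndarray]:
        starts = list(self.segment_starts) + [len(self.codes)]
        return [self.codes[a:b] for a, b in zip(starts[:-1], starts[1:]) if b - a > 0]

    def histogram(self) -> np.ndarray:
        """Empirical symbol distribution over the 4-letter alphabet."""
        counts = np.bincount(self.codes, minlength=ALPHABET_SIZE)
        return counts / max(1, len(self.codes))


def symbol_labels(codes: np.ndarray) -> list[str]:
    return [ALPHABET[c] for c in np.asarray(codes)]


def _signs_with_ties(
    v: np.ndarray, tie_rule: str, rng: np.random.Generator | None
) -> np.ndarray:
    """Map a real series to {0, 1} = {decreasing, increasing}, resolving zeros."""
    s = np.sign(v)
    zeros = s == 0
    if zeros.any():
        if tie_rule == "carry":
            # plateau continues the preceding trend; leading plateau is "-"
            filled = s.copy()
            filled[0] = filled[0] if filled[0] != 0 else -1.0
            nz = filled != 0
            idx = np.maximum.accumulate(np.where(nz, np.arange(len(s)), 0))
            s = filled[idx]
        elif tie_rule == "random":
            if rng is None:
                raise ValueError("tie_rule='random' requires a seeded rng")
            s[zeros] = rng.choice([-1.0, 1.0], size=int(zeros.sum()))
        else:
            raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return (s > 0).astype(np.int64)


def symbolize(
    kin: KinematicSeries,
    tie_rule: str = "carry",
    rng: np.random.Generator | None = None,
) -> SymbolSeries:
    """Encode a kinematic series into the 4-symbol joint alphabet.

    Symbols are assigned per acceleration sample (per frame).  The encoding
    depends only on the signs of the accelerations, so it is invariant under
    any positive rescaling of speed or turn rate.

    Parameters
    ----------
    kin
        Kinematic series with aligned ``lin_accel`` / ``ang_accel``.
    tie_rule
        "carry" (default): an exact-zero acceleration continues the previous
        sign of that channel (deterministic).  "random": resolved by a coin
        flip from ``rng``.
    """
    if len(kin) < 1:
        raise ValueError("insufficient data: empty kinematic series")
    # ties are resolved per segment so a plateau never carries across a gap
    codes = np.empty(len(kin), dtype=np.int64)
    starts = list(kin.segment_starts) + [len(kin)]
    for a, b in zip(starts[:-1], starts[1:]):
        if b <= a:
            continue
        sp_up = _signs_with_ties(kin.lin_accel[a:b], tie_rule, rng)
        tr_up = _signs_with_ties(kin.ang_accel[a:b], tie_rule, rng)
        codes[a:b] = 2 * sp_up + tr_up
    return SymbolSeries(
        t=kin.t,
        codes=codes,
        frame_rate=kin.frame_rate,
        subject_id=kin.subject_id,
        segment_starts=kin.segment_starts,
    )
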