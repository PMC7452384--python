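"""Plug-in symbolic transfer entropy and net transfer entropy.

Transfer entropy from a source process X to a destination process Y with
history length k is

    TE_{X->Y} = sum p(y_{t+1}, y_t^(k), x_t^(k))
                    log[ p(y_{t+1} | y_t^(k), x_t^(k)) / p(y_{t+1} | y_t^(k)) ]

estimated by plugging in the empirical (maximum-likelihood) joint histogram
over the 4-symbol alphabet, with the convention 0 * log(.) = 0.  No bias
correction is applied to point estimates: significance is assessed against
surrogate distributions that share the same finite-sample bias (see
:mod:`dyadkit.surrogates`).

Units default to bits (log base 2); natural log is available via ``base``.
When a series was split into segments by gap handling, joint counts are
pooled across segments without ever bridging a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .symbolize import ALPHABET_SIZE, SymbolSeries

__all__ = [
    "TEResult",
    "NetTEResult",
    "transfer_entropy",
    "net_transfer_entropy",
    "te_from_segments",
]

LOW_N_THRESHOLD = 100


@dataclass
class TEResult:
    """Directional transfer entropy with its estimation metadata."""

    te: float
    direction: tuple[str, str]  # (source id, destination id)
    history_k: int
    n_samples: int
    base: float = 2.0
    low_n: bool = False

    def __post_init__(self) -> None:
        if self.te < 0:
            raise ValueError("transfer entropy must be non-negative")

    def to_record(self) -> dict:
        return {
            "source": self.direction[0],
            "destination": self.direction[1],
            "te": self.te,
            "k": self.history_k,
            "n": self.n_samples,
            "log_base": self.base,
        }


@dataclass
class NetTEResult:
    """Signed TE asymmetry of a pair: te(small->large) - te(large->small).

    A positive value means the small subject's past is the more informative
    one — it dominates the interaction.
    """

    net_te: float
    small_to_large: TEResult
    large_to_small: TEResult

    def to_record(self) -> dict:
        return {
            "net_te": self.net_te,
            "small_to_large": self.small_to_large.to_record(),
            "large_to_small": self.large_to_small.to_record(),
        }


def _history_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Encode length-k histories ending at each t >= k-1 as a single integer."""
    n = len(codes)
    out = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        out = out * ALPHABET_SIZE + codes[j : n - k + 1 + j]
    return out


def te_from_segments(
    x_segments: list[np.ndarray],
    y_segments: list[np.ndarray],
    k: int = 1,
    base: float = 2.0,
) -> tuple[float, int]:
    """Plug-in TE from pooled joint counts over aligned segment pairs.

    Returns ``(te, n_joint_samples)``.  Segments shorter than k+1 contribute
    nothing.  This is the computational core shared by :func:`transfer_entropy`
    and the surrogate machinery.
    """
    if k < 1:
        raise ValueError("history length k must be >= 1")
    h = ALPHABET_SIZE**k
    counts = np.zeros(ALPHABET_SIZE * h * h, dtype=np.int64)
    n_total = 0
    for xs, ys in zip(x_segments, y_segments):
        if len(xs) != len(ys):
            raise ValueError("alignment error: segment lengths differ")
        if len(ys) < k + 1:
            continue
        y_next = ys[k:]
        y_hist = _history_codes(ys[:-1], k)
        x_hist = _history_codes(xs[:-1], k)
        joint = (y_next * h + y_hist) * h + x_hist
        counts += np.bincount(joint, minlength=len(counts))
        n_total += len(y_next)
    if n_total == 0:
        raise ValueError("insufficient overlap: no segment has > k samples")
    c = counts.reshape(ALPHABET_SIZE, h, h).astype(float)
    c_yh_xh = c.sum(axis=0)                 # (yh, xh)
    c_yf_yh = c.sum(axis=2)                 # (yf, yh)
    c_yh = c_yh_xh.sum(axis=1)              # (yh,)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c * c_yh[None, :, None]) / (c_yh_xh[None, :, :] * c_yf_yh[:, :, None])
        term = np.where(c > 0, c * np.log(ratio), 0.0)
    te = float(term.sum() / n_total / np.log(base))
    # clamp tiny negative round-off
    return max(te, 0.0), n_total


def transfer_entropy(
    src: SymbolSeries,
    dst: SymbolSeries,
    k: int = 1,
    base: float = 2.0,
) -> TEResult:
    """Symbolic transfer entropy from ``src`` to ``dst``.

    The two series must share a clock (same length and segment structure).
    With fewer than 100 joint samples the result is flagged ``low_n`` — the
    64-cell joint histogram (k=1) is then badly undersampled.
    """
    if len(src) != len(dst):
        raise ValueError("alignment error: series lengths differ")
    if src.segment_starts != dst.segment_starts:
        raise ValueError("alignment error: segment structures differ")
    te, n = te_from_segments(src.segments(), dst.segments(), k=k, base=base)
    return TEResult(
        te=te,
        direction=(src.subject_id, dst.subject_id),
        history_k=k,
        n_samples=n,
        base=base,
        low_n=n < LOW_N_THRESHOLD,
    )


def net_transfer_entropy(
    small: SymbolSeries,
    large: SymbolSeries,
    k: int = 1,
    base: float = 2.0,
) -> NetTEResult:
    """Net TE of a pair: te(small -> large) - te(large -> small).

    Antisymmetric under swapping the two roles; carries both components.
    """
    s2l = transfer_entropy(small, large, k=k, base=base)
    l2s = transfer_entropy(large, small, k=k, base=base)
    return NetTEResult(net_te=s2l.te - l2s.te, small_to_large=s2l, large_to_small=l2s)
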