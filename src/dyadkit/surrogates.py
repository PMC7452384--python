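"""Surrogate-data generation and non-parametric permutation tests.

Significance of a coupling statistic (transfer entropy, net transfer
entropy, cross-correlation maximum, leader-follower lag) is assessed
against a surrogate distribution obtained by destroying the cross-coupling
between the members of each pair while preserving each member's own
dynamics.  The default surrogate is a circular time-rotation of one series
by a uniform random offset in [0.1 n, 0.9 n] frames: it preserves the
rotated series' marginal distribution and autocorrelation, which makes it
the conservative null for transfer entropy.  Within-series shuffling and
cross-pair swapping are provided as alternatives, and every result records
the method and seed used.

The tested statistic is a single number per condition — typically the
across-pair average — and each surrogate replicate rebuilds that average
from one fresh surrogate per pair, mirroring how the observed statistic was
formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PermutationTestResult",
    "make_surrogate_pair",
    "permutation_test",
    "SURROGATE_METHODS",
]

SURROGATE_METHODS = ("rotate", "shuffle", "swap")

MIN_SURROGATE_LEN = 10


@dataclass
class PermutationTestResult:
    """Observed statistic, surrogate quantiles, and permutation p-value.

    ``quantile_95`` is the one-tailed (upper) threshold; ``quantile_2_5`` and
    ``quantile_97_5`` bracket the two-tailed acceptance region.  The p-value
    uses the add-one estimator, so it can never be exactly zero:
    one-tailed p = (1 + #{surrogate >= observed}) / (1 + n_surrogates),
    two-tailed p = min(1, 2 * min(upper tail, lower tail)).
    """

    observed: float
    n_surrogates: int
    quantile_95: float
    quantile_2_5: float
    quantile_97_5: float
    p_value: float
    tail: str  # "one_tailed_upper" | "two_tailed"
    seed: int | None = None
    method: str = "rotate"
    surrogate_mean: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_record(self) -> dict:
        return {
            "observed": self.observed,
            "n_surrogates": self.n_surrogates,
            "quantile_95": self.quantile_95,
            "quantile_2_5": self.quantile_2_5,
            "quantile_97_5": self.quantile_97_5,
            "p_value": self.p_value,
            "tail": self.tail,
            "seed": self.seed,
            "surrogate_method": self.method,
        }


def _series_array(s) -> np.ndarray:
    """Accept SymbolSeries / KinematicSeries-like objects or plain arrays."""
    if hasattr(s, "codes"):
        return s.codes
    return np.asarray(s)


def _rebuild(template, arr: np.ndarray):
    """Return a surrogate carrying the same container type as the template."""
    if hasattr(template, "codes"):
        from dataclasses import replace

        return replace(template, codes=arr)
    return arr


def make_surrogate_pair(
    a,
    b,
    method: str = "rotate",
    rng: np.random.Generator | None = None,
    pool: Sequence | None = None,
):
    """Return ``(a, b*)`` with the cross-coupling between a and b destroyed.

    ``b*`` preserves b's marginal distribution; with the default circular
    rotation it also preserves b's autocorrelation.  Offset 0 (identity) is
    excluded from the admissible rotations, so ``b* != b`` is guaranteed for
    any non-constant series.

    ``pool`` is required for method "swap": b is replaced by the b-member of
    a different, randomly chosen pair.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    arr = _series_array(b)
    n = len(arr)
    if n < MIN_SURROGATE_LEN:
        raise ValueError("insufficient data: series shorter than 10 samples")
    if method == "rotate":
        lo = max(1, int(np.ceil(0.1 * n)))
        hi = int(np.floor(0.9 * n))
        offset = int(rng.integers(lo, hi + 1))
        out = np.roll(arr, offset)
    elif method == "shuffle":
        out = rng.permutation(arr)
    elif method == "swap":
        if pool is None or len(pool) < 2:
            raise ValueError("method 'swap' needs a pool of >= 2 pairs")
        others = [p for p in pool if _series_array(p[1]) is not arr]
        donor = others[int(rng.integers(len(others)))]
        out = _series_array(donor[1]).copy()
        m = min(len(out), len(_series_array(a)))
        out = out[:m]
    else:
        raise ValueError(f"unknown surrogate method {method!r}")
    return a, _rebuild(b, out)


def permutation_test(
    stat_fn: Callable[[list], float],
    pairs: list,
    n_surrogates: int = 20_000,
    tail: str = "one_tailed_upper",
    rng: np.random.Generator | None = None,
    method: str = "rotate",
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test of a coupling statistic against surrogate pairs.

    Parameters
    ----------
    stat_fn
        Maps a list of aligned ``(a, b)`` pairs to a scalar — e.g. the
        trial-averaged transfer entropy or the trial-averaged lag.
    pairs
        The real pairs.  Each surrogate replicate draws one surrogate per
        pair and re-applies ``stat_fn`` to the full surrogate set, so the
        null replicates the observed statistic's averaging structure.
    n_surrogates
        Number of surrogate replicates (20,000 by default; values below 100
        trigger an "unstable quantiles" warning).
    tail
        "one_tailed_upper" for non-negative coupling statistics (TE,
        correlation maxima); "two_tailed" for signed ones (net TE, lag).
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    if tail not in ("one_tailed_upper", "two_tailed"):
        raise ValueError(f"unknown tail {tail!r}")
    if rng is None:
        if seed is None:
            raise ValueError("supply rng or seed")
        rng = np.random.default_rng(seed)
    if n_surrogates < 100:
        import warnings

        warnings.warn("unstable quantiles: n_surrogates < 100", stacklevel=2)

    observed = float(stat_fn(pairs))
    surr = np.empty(n_surrogates)
    for i in range(n_surrogates):
        surr_pairs = [
            make_surrogate_pair(a, b, method=method, rng=rng, pool=pairs)
            for a, b in pairs
        ]
        surr[i] = stat_fn(surr_pairs)

    q95, q2_5, q97_5 = np.quantile(surr, [0.95, 0.025, 0.975])
    n1 = n_surrogates + 1
    upper = (1 + int(np.sum(surr >= observed))) / n1
    lower = (1 + int(np.sum(surr <= observed))) / n1
    p = upper if tail == "one_tailed_upper" else min(1.0, 2.0 * min(upper, lower))
    return PermutationTestResult(
        observed=observed,
        n_surrogates=n_surrogates,
        quantile_95=float(q95),
        quantile_2_5=float(q2_5),
        quantile_97_5=float(q97_5),
        p_value=p,
        tail=tail,
        seed=seed,
        method=method,
        surrogate_mean=float(surr.mean()),
    )
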