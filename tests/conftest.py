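"""Shared fixtures: small synthetic dyads and symbol chains.

Everything is generated at test time from seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import dyadkit as dk


@pytest.fixture(scope="session")
def coupled_dyad():
    """One strongly coupled dyad (small leads) at desk scale."""
    cfg = dk.DyadSimConfig(
        duration=120.0, frame_rate=10.0,
        coupling_strength=0.6, coupling_lag=0.1, seed=42,
    )
    return dk.simulate_dyad(cfg)


@pytest.fixture(scope="session")
def uncoupled_dyad():
    """Two statistically independent swimmers."""
    cfg = dk.DyadSimConfig(
        duration=120.0, frame_rate=10.0,
        coupling_strength=0.0, attraction_gain=0.0, seed=42,
    )
    return dk.simulate_dyad(cfg)


@pytest.fixture(scope="session")
def coupled_symbols(coupled_dyad):
    small, large = coupled_dyad
    return (
        dk.symbolize(dk.compute_kinematics(small)),
        dk.symbolize(dk.compute_kinematics(large)),
    )


def make_trajectory(x, y, frame_rate=10.0, bounds=None, **kw):
    """Helper: wrap plain position arrays into a Trajectory."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if bounds is None:
        if np.isfinite(x).any() and np.isfinite(y).any():
            bounds = (
                np.nanmin(x) - 1.0, np.nanmax(x) + 1.0,
                np.nanmin(y) - 1.0, np.nanmax(y) + 1.0,
            )
        else:
            bounds = (0.0, 1.0, 0.0, 1.0)
    t = np.arange(len(x)) / frame_rate
    return dk.Trajectory(t=t, x=x, y=y, frame_rate=frame_rate, arena_bounds=bounds, **kw)
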