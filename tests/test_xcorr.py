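"""Cross-correlation lag scan, similarity index, and leader-follower tests."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import dyadkit as dk
from dyadkit.xcorr import windowed_xcorr_arrays, xcorr_arrays

from conftest import make_trajectory


def exhaustive_lag_scan(a, b, max_lag):
    """Oracle: independent double loop with scipy's Pearson at every lag."""
    n = len(a)
    best = (-np.inf, 0)
    for m in sorted(range(-max_lag, max_lag + 1), key=lambda q: (abs(q), -q)):
        if m >= 0:
            r = pearsonr(a[: n - m], b[m:]).statistic
        else:
            r = pearsonr(a[-m:], b[: n + m]).statistic
        if r > best[0]:
            best = (r, m)
    return best


class TestNormalizedXcorr:
    def test_identical_series(self):
        a = np.sin(np.linspace(0, 20, 300))
        res = dk.normalized_xcorr(a, a, max_lag=1.0, frame_rate=10.0)
        assert res.max_corr == pytest.approx(1.0)
        assert res.lag == 0.0

    def test_pure_delay_recovers_lag(self):
        rng = np.random.default_rng(0)
        a = np.cumsum(rng.normal(size=400))
        b = np.roll(a, 5)  # b is a delayed by 5 frames at 10 Hz
        res = dk.normalized_xcorr(a[20:-20], b[20:-20], max_lag=1.0, frame_rate=10.0)
        assert res.max_corr == pytest.approx(1.0, abs=1e-3)
        assert res.lag == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=150)
        b = rng.normal(size=150)
        got_corr, got_lag = xcorr_arrays(a, b, 12)
        exp_corr, exp_lag = exhaustive_lag_scan(a, b, 12)
        assert got_corr == pytest.approx(exp_corr, abs=1e-12)
        assert got_lag == exp_lag

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = np.cumsum(rng.normal(size=300))
        b = np.cumsum(rng.normal(size=300))
        fwd = xcorr_arrays(a, b, 20)
        rev = xcorr_arrays(b, a, 20)
        assert fwd[0] == pytest.approx(rev[0], abs=1e-12)
        assert fwd[1] == -rev[1]

    def test_white_noise_max_corr_near_null_extreme(self):
        """Independent noise: observed max within the Monte-Carlo null range."""
        rng = np.random.default_rng(4)
        n, max_lag = 6_000, 10
        observed = xcorr_arrays(rng.normal(size=n), rng.normal(size=n), max_lag)[0]
        null = [
            xcorr_arrays(rng.normal(size=n), rng.normal(size=n), max_lag)[0]
            for _ in range(50)
        ]
        # the scan max of 21 null correlations (each sd ~ 1/sqrt(n)) stays tiny
        assert observed < 3.0 * np.max(null)
        assert observed < 0.1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            xcorr_arrays(np.ones(100), np.arange(100.0), 5)

    def test_windowed_scan_agrees_with_per_window_loop(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=600)
        b = rng.normal(size=600)
        corr, lag = windowed_xcorr_arrays(a, b, wlen=200, max_lag_frames=15)
        for w in range(3):
            ec, el = exhaustive_lag_scan(a[w * 200 : (w + 1) * 200], b[w * 200 : (w + 1) * 200], 15)
            assert corr[w] == pytest.approx(ec, abs=1e-12)
            assert lag[w] == el


class TestSimilarityIndex:
    def _dyad_with_channel(self, delay, seed=0, **channel_kw):
        cfg = dk.DyadSimConfig(
            duration=120.0, frame_rate=10.0, coupling_strength=0.0,
            attraction_gain=0.0, seed=seed,
        )
        fish, _ = dk.simulate_dyad(cfg)
        replica = dk.teleport_channel(
            fish, dk.ChannelConfig(delay=delay, **channel_kw),
            rng=np.random.default_rng(seed + 1),
        )
        return fish, replica

    def test_identical_replica_perfect_similarity(self):
        fish, _ = self._dyad_with_channel(0.0)
        res = dk.similarity_index(fish, fish, window=20.0)
        assert np.allclose(res.similarity, 1.0)
        assert np.allclose(res.lag, 0.0)
        assert res.success.all()
        assert res.coverage_fraction == 1.0

    def test_delay_below_threshold_succeeds(self):
        fish, replica = self._dyad_with_channel(0.15)
        res = dk.similarity_index(fish, replica, window=20.0)
        valid = np.isfinite(res.similarity)
        assert res.success[valid].all()
        assert np.nanmean(res.lag) == pytest.approx(0.15, abs=0.05)

    def test_delay_above_threshold_fails(self):
        fish, replica = self._dyad_with_channel(0.30)
        res = dk.similarity_index(fish, replica, window=20.0)
        valid = np.isfinite(res.similarity)
        assert not res.success[valid].any()
        assert np.nanmean(res.lag) == pytest.approx(0.30, abs=0.05)

    def test_rigid_translation_invariance(self):
        fish, replica = self._dyad_with_channel(0.1)
        shifted_fish = make_trajectory(fish.x + 50.0, fish.y - 20.0, frame_rate=10.0)
        shifted_replica = make_trajectory(replica.x + 50.0, replica.y - 20.0, frame_rate=10.0)
        a = dk.similarity_index(fish, replica)
        b = dk.similarity_index(shifted_fish, shifted_replica)
        assert np.allclose(a.similarity, b.similarity, equal_nan=True)

    def test_empty_replica_rejected(self, coupled_dyad):
        fish, other = coupled_dyad
        bad = make_trajectory(other.x[:50], other.y[:50], frame_rate=10.0)
        with pytest.raises(ValueError, match="alignment|replica"):
            dk.similarity_index(fish, bad)


class TestLeaderFollower:
    def _study_pairs(self, c, n_pairs=6, seed=0, duration=300.0):
        pairs = []
        for i in range(n_pairs):
            cfg = dk.DyadSimConfig(
                duration=duration, frame_rate=10.0, coupling_strength=c,
                attraction_gain=0.0 if c == 0 else 0.8,
                coupling_lag=0.1, seed=seed + i,
            )
            s, l = dk.simulate_dyad(cfg)
            pairs.append((dk.compute_kinematics(s), dk.compute_kinematics(l)))
        return pairs

    def test_small_leader_gives_positive_lag(self):
        # narrow scan: with 6 pairs x 300 s the null argmax over a +/-1 s
        # window is too dispersed to resolve a 0.1-s lead
        pairs = self._study_pairs(0.8, seed=10)
        corr_t, lag_t = dk.leader_follower_summary(
            pairs, channel="speed", max_lag=0.3, n_surrogates=300, seed=0
        )
        assert lag_t.observed == pytest.approx(0.1, abs=0.05)
        assert lag_t.p_value < 0.05
        assert corr_t.p_value < 0.05

    def test_large_leader_negates_lag(self):
        pairs = []
        for i in range(6):
            cfg = dk.DyadSimConfig(
                duration=300.0, frame_rate=10.0, coupling_strength=0.8,
                coupling_lag=0.1, leader="large", seed=10 + i,
            )
            s, l = dk.simulate_dyad(cfg)
            pairs.append((dk.compute_kinematics(s), dk.compute_kinematics(l)))
        _, lag_t = dk.leader_follower_summary(
            pairs, channel="speed", max_lag=0.3, n_surrogates=300, seed=0
        )
        assert lag_t.observed == pytest.approx(-0.1, abs=0.05)
        assert lag_t.p_value < 0.05

    def test_uncoupled_lag_not_significant(self):
        pairs = self._study_pairs(0.0, seed=30, duration=120.0)
        _, lag_t = dk.leader_follower_summary(
            pairs, channel="speed", n_surrogates=300, seed=1
        )
        assert lag_t.p_value > 0.05
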