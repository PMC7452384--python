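"""Transfer entropy: brute-force oracle equivalence and analytic limits."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadkit as dk
from dyadkit.infotheory import te_from_segments, transfer_entropy
from dyadkit.symbolize import SymbolSeries


def brute_force_te(x, y, k=1, base=2.0):
    """Independent plug-in TE: explicit loop over all 4^(2k+1) outcomes.

    Counts every (future, y-history, x-history) combination by direct
    enumeration and sums p * log(p(y+|yh,xh) / p(y+|yh)) term by term.
    """
    x = list(x)
    y = list(y)
    n = len(y)
    samples = [
        (y[t], tuple(y[t - k : t]), tuple(x[t - k : t])) for t in range(k, n)
    ]
    big_n = len(samples)
    te = 0.0
    for yf in range(4):
        for yh in product(range(4), repeat=k):
            for xh in product(range(4), repeat=k):
                c_full = sum(1 for s in samples if s == (yf, yh, xh))
                if c_full == 0:
                    continue
                c_yh_xh = sum(1 for s in samples if s[1] == yh and s[2] == xh)
                c_yf_yh = sum(1 for s in samples if s[0] == yf and s[1] == yh)
                c_yh = sum(1 for s in samples if s[1] == yh)
                p_cond_full = c_full / c_yh_xh
                p_cond_marg = c_yf_yh / c_yh
                te += (c_full / big_n) * math.log(p_cond_full / p_cond_marg, base)
    return te


def sym(codes):
    codes = np.asarray(codes, dtype=np.int64)
    return SymbolSeries(t=np.arange(len(codes), dtype=float), codes=codes)


class TestPluginEqualsBruteForce:
    @pytest.mark.parametrize("k", [1, 2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_series(self, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=400)
        y = rng.integers(0, 4, size=400)
        te, n = te_from_segments([x], [y], k=k)
        assert n == 400 - k
        assert te == pytest.approx(brute_force_te(x, y, k=k), abs=1e-12)

    def test_coupled_chain_instance(self):
        xs, ys = dk.simulate_coupled_chain(0.7, 500, rng=3)
        te, _ = te_from_segments([xs.codes], [ys.codes], k=1)
        assert te == pytest.approx(brute_force_te(xs.codes, ys.codes), abs=1e-12)

    def test_natural_log_base(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 4, size=300)
        y = rng.integers(0, 4, size=300)
        te, _ = te_from_segments([x], [y], k=1, base=math.e)
        assert te == pytest.approx(brute_force_te(x, y, base=math.e), abs=1e-12)


class TestAnalyticLimits:
    def test_perfect_copy_chain_reaches_two_bits(self):
        # y[t+1] = x[t] exactly, x i.i.d. uniform: TE = log2(4) = 2 bits
        xs, ys = dk.simulate_coupled_chain(1.0, 20_000, rng=0)
        r = dk.transfer_entropy(xs, ys, k=1)
        assert r.te == pytest.approx(2.0, abs=0.01)

    def test_self_te_is_zero(self):
        xs, _ = dk.simulate_coupled_chain(0.5, 1_000, rng=1)
        assert dk.transfer_entropy(xs, xs, k=1).te == pytest.approx(0.0, abs=1e-12)

    def test_independent_series_small_te(self):
        xs, ys = dk.simulate_coupled_chain(0.0, 20_000, rng=2)
        # plug-in bias ~ 36 / (2 n ln 2) ~ 1.3e-3 bits at n = 20,000
        assert dk.transfer_entropy(xs, ys).te < 5e-3

    def test_te_bounded_by_alphabet_entropy(self, coupled_symbols):
        small, large = coupled_symbols
        r = dk.transfer_entropy(small, large, k=1)
        assert 0.0 <= r.te <= 2.0


class TestNetTE:
    def test_identical_series_net_zero(self):
        xs, _ = dk.simulate_coupled_chain(0.3, 500, rng=4)
        net = dk.net_transfer_entropy(xs, xs)
        assert net.net_te == 0.0

    def test_copy_chain_net_plus_two_bits(self):
        xs, ys = dk.simulate_coupled_chain(1.0, 20_000, rng=5)
        net = dk.net_transfer_entropy(xs, ys)
        # information flows only from the copied-from series
        assert net.net_te == pytest.approx(2.0, abs=0.05)
        assert net.net_te == net.small_to_large.te - net.large_to_small.te

    def test_swapping_roles_negates_net_te(self, coupled_symbols):
        small, large = coupled_symbols
        fwd = dk.net_transfer_entropy(small, large)
        rev = dk.net_transfer_entropy(large, small)
        assert fwd.net_te == pytest.approx(-rev.net_te, abs=1e-12)


@given(perm_seed=st.integers(0, 1000), data_seed=st.integers(0, 1000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_relabeling_invariance(perm_seed, data_seed):
    """TE is unchanged by a consistent permutation of the alphabet."""
    rng = np.random.default_rng(data_seed)
    x = rng.integers(0, 4, size=300)
    y = rng.integers(0, 4, size=300)
    perm = np.random.default_rng(perm_seed).permutation(4)
    te0, _ = te_from_segments([x], [y], k=1)
    te1, _ = te_from_segments([perm[x]], [perm[y]], k=1)
    assert te1 == pytest.approx(te0, abs=1e-12)


def test_monotone_in_coupling_strength():
    """Estimated TE grows with chain coupling c, averaged over 20 seeds."""
    means = []
    for c in (0.0, 0.2, 0.4, 0.8):
        vals = []
        for seed in range(20):
            xs, ys = dk.simulate_coupled_chain(c, 2_000, rng=seed)
            vals.append(dk.transfer_entropy(xs, ys).te)
        means.append(np.mean(vals))
    assert all(a < b for a, b in zip(means, means[1:]))


class TestContracts:
    def test_segment_pooling_never_bridges_gaps(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 4, size=200)
        y = rng.integers(0, 4, size=200)
        pooled, n = te_from_segments([x[:100], x[100:]], [y[:100], y[100:]], k=1)
        # pooling two segments discards the joint sample that would bridge them
        assert n == 198
        whole, n2 = te_from_segments([x], [y], k=1)
        assert n2 == 199

    def test_misaligned_lengths_raise(self):
        a = sym(np.zeros(50, dtype=int))
        b = sym(np.zeros(60, dtype=int))
        with pytest.raises(ValueError, match="alignment"):
            transfer_entropy(a, b)

    def test_low_n_flagged(self):
        rng = np.random.default_rng(12)
        a = sym(rng.integers(0, 4, size=40))
        b = sym(rng.integers(0, 4, size=40))
        assert transfer_entropy(a, b).low_n is True

    def test_serialization_record(self, coupled_symbols):
        small, large = coupled_symbols
        rec = dk.transfer_entropy(small, large).to_record()
        assert set(rec) == {"source", "destination", "te", "k", "n", "log_base"}
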