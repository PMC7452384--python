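# dyadkit

Information-theoretic analysis of dyadic animal interactions from planar
trajectory time-series — built for experiments in which a live subject
interacts either with a conspecific or with a robotic replica that mirrors,
over a noisy delayed relay, the motion of a remotely located partner.

`dyadkit` answers three questions a behavioral experimenter asks of such
data:

1. **Do the two subjects influence each other, and who drives whom?**
   Symbolic transfer entropy between the subjects' locomotion, with
   surrogate-data permutation tests.
2. **Who moves first?**  Lag-scanned normalized cross-correlation of speed
   and turn-rate series; the sign of the lag at the correlation maximum
   identifies the leader.
3. **How faithful is the replica?**  A windowed similarity index between a
   subject's trajectory and its replica's, with an explicit success rule.

Because the original recordings may not be at hand, the package ships a
synthetic generator of coupled swimmers with known ground truth (coupling
strength, coupling lag, leader identity, relay-channel noise), so the whole
chain — and its statistical calibration — is testable end to end.

## The statistics

**Kinematics and symbolization.**  From per-frame positions the package
derives speed `v_t` and (unsigned) turn rate `ω_t`, then encodes each frame
by one of four symbols from the signs of the linear and angular
accelerations: `--`, `-+`, `+-`, `++` (speed decreasing/increasing × turn
rate decreasing/increasing).  This coarse alphabet trades resolution for
well-sampled histograms on 10-minute sessions.

**Transfer entropy.**  For symbol processes X (source) and Y (destination)
with history length k (default 1),

    TE(X→Y) = Σ p(y_{t+1}, y_t^(k), x_t^(k)) ·
              log₂ [ p(y_{t+1} | y_t^(k), x_t^(k)) / p(y_{t+1} | y_t^(k)) ]

estimated by the plug-in (maximum-likelihood) histogram over the 4-letter
alphabet, in bits.  Net TE of a (small, large) pair is
`TE(small→large) − TE(large→small)`; a positive value means the small
subject drives the interaction.

**Surrogate permutation tests.**  The tested statistic is the across-pair
average; its null distribution comes from circularly time-rotating one
member of each pair (preserving marginals and autocorrelation, destroying
coupling), re-averaging, and repeating 20,000 times (default).  P-values
use the add-one estimator; one-tailed upper for TE and correlation maxima,
two-tailed for signed quantities (net TE, lag).

**Leader–follower lag.**  Per pair, the Pearson cross-correlation of the
speed (or turn-rate) series is recomputed on the overlapping support at
every integer-frame lag up to ±1 s, within non-overlapping 20-s windows;
the per-pair statistic is the window-averaged maximum and its signed lag
(positive = the small subject precedes).

**Similarity index.**  Per 20-s window, the minimum over the X and Y
coordinate channels of the maximum normalized cross-correlation between
subject and replica; a window is a *success* when similarity ≥ 0.95 at a
lag ≤ 0.2 s.

## Worked example

Simulate a 12-pair study of coupled dyads (coupling strength c = 0.6 from
the small leader to the large follower at a 0.1-s lag, 10-minute sessions
at 10 Hz) and run the two headline analyses:

```python
import numpy as np
import dyadkit as dk
from dyadkit.infotheory import te_from_segments

syms, kins = [], []
for i in range(12):
    cfg = dk.DyadSimConfig(duration=600.0, frame_rate=10.0,
                           coupling_strength=0.6, coupling_lag=0.1, seed=100 + i)
    small, large = dk.simulate_dyad(cfg)
    ks, kl = dk.compute_kinematics(small), dk.compute_kinematics(large)
    kins.append((ks, kl))
    syms.append((dk.symbolize(ks), dk.symbolize(kl)))

def mean_net(ps):
    return float(np.mean([te_from_segments(a.segments(), b.segments())[0]
                          - te_from_segments(b.segments(), a.segments())[0]
                          for a, b in ps]))

rng = np.random.default_rng(0)
net = dk.permutation_test(mean_net, syms, n_surrogates=1000,
                          tail="two_tailed", rng=rng)
corr_t, lag_t = dk.leader_follower_summary(kins, channel="speed",
                                           n_surrogates=1000, rng=rng)
```

Output:

```
net TE          : +0.2987 bits  (2.5%, 97.5%) = (-0.0008, +0.0008), p = 0.001998
speed xcorr max : 0.942   (95% = 0.167), p = 0.000999
speed lag       : +0.100 s (2.5%, 97.5%) = (-0.076, +0.079), p = 0.01199
```

Reading: information flows predominantly from the small to the large
subject (net TE far above the two-tailed surrogate band), the speed series
are strongly coupled, and the small subject leads by +0.100 s — the
generator's 0.1-s coupling lag, recovered exactly on the 10-Hz frame grid.

The same analysis runs from the shell over trajectory CSV files:

```bash
dyadkit simulate study/ --n-pairs 12 --duration 600 --frame-rate 10 --seed 0
dyadkit run-study study/study.yaml --n-surrogates 1000
dyadkit report study/results/study_report.json
```

`run-study` writes `transfer_entropy.csv` and `cross_correlation.csv` (one
row per condition: statistic, surrogate quantiles, p-value) plus
`similarity.csv` and a full JSON report.

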