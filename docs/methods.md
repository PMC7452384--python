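# Methods

This note documents the models, estimators, parameter choices, and known
limitations behind `dyadkit`, in the order data flows through the package.

## Kinematics

A trajectory is a strictly increasing time base `t` with planar positions
`(x, y)` inside a rectangular arena; missing frames are NaN.

* **Gap handling** (`fill_gaps`): dropout runs spanning at most `max_gap`
  seconds (default 0.5 s) are linearly interpolated; longer runs split the
  session into segments that every downstream statistic treats
  independently — joint symbol counts, correlations and surrogate rotations
  never bridge a split.
* **Speed** is the forward finite difference of position; the velocity
  between frames i and i+1 is assigned to `t_i`.  **Heading** is the
  direction of the same displacement; zero-displacement steps carry the
  last defined heading (heading is undefined while stationary, and any
  fixed convention such as `atan2(0,0) = 0` would break invariance under
  rotation of the camera frame).
* **Turn rate** is by default the unsigned angular speed
  `|wrap(Δheading)|/Δt` with wrapping to (−π, π].  Unsigned is the default
  because the symbolization needs "turn rate increasing/decreasing" to be
  meaningful irrespective of turning direction; a signed variant is behind
  `signed_turn_rate=True`.
* **Accelerations** are centred differences (one-sided at segment ends) of
  the speed and turn-rate series on their shared clock, so the two series
  entering the joint symbolization carry no relative phase shift.
* **Smoothing**: a moving average over `smooth_window` seconds (default
  0.1 s ≈ 3 samples at 30 Hz) is applied to speed and turn rate before
  differentiation.  Real tracking data is pixel-quantized; without mild
  smoothing the acceleration signs would be dominated by quantization
  chatter.  `smooth_window=0` disables it (the closed-form oracle tests run
  unsmoothed).

Units are carried through unchanged (lengths in whatever unit the arena is
specified in — centimetres throughout the synthetic generator; angles in
radians; times in seconds).  The frame rate is always taken from the
metadata/timestamps, never assumed.

## Symbolization

Each frame maps to one of four symbols from the sign pair
(linear acceleration, angular acceleration): `--`, `-+`, `+-`, `++`,
encoded as integers 0–3.  Exact zeros carry the preceding sign of that
channel (deterministic; a plateau continues the trend; the leading sign is
`-`).  A seeded random-sign rule is available; in floating-point kinematics
plateaus are rare, so the choice is benign — but the default must be
deterministic for bit-reproducibility.  Symbols are per frame, not per
behavioral bout; window-aggregated symbolization was considered and
rejected because it discards the short-latency structure the lag analysis
reads.

## Transfer entropy

Plug-in (maximum-likelihood) estimate over the 4-letter alphabet with
history length `k` (default 1) and log base 2 (bits); `0·log(·) = 0` for
empty cells.  With k = 1 the joint histogram has 4³ = 64 cells, well
sampled by a 10-minute session even at 10 Hz (≈ 6,000 samples).  No bias
correction is applied: the permutation test compares the observed value
against surrogates computed by the *same* estimator on data of the same
length and marginals, so the finite-sample bias cancels in the comparison.
The estimator's bias at independence is ≈ 36/(2·N·ln 2) bits (the χ²
degrees of freedom of the 4×4×4 table), ~5·10⁻⁴ bits at N = 50,000 — the
acceptance script verifies the estimate at zero coupling stays below 0.01
bits.

Both `k` and the log base are configuration parameters (`analyze-te
--log-base`, `StudyConfig.log_base`): published TE magnitudes depend on the
unit convention, so reproducing someone else's table may require scanning
both bases.

`net TE = TE(small→large) − TE(large→small)`, exactly antisymmetric under
swapping roles.  Estimates from fewer than 100 joint samples are flagged
`low_n`.

## Surrogates and permutation tests

* **Null model**: circular rotation of one series by a uniform random
  offset in [0.1·n, 0.9·n] frames (offset 0 excluded).  Rotation preserves
  the rotated series' marginal distribution *and* autocorrelation while
  destroying its coupling to the partner — the conservative null for
  transfer entropy on autocorrelated behavior.  Within-series shuffling
  (destroys autocorrelation too) and cross-pair swapping are provided as
  alternatives; every result records the method and seed.
* **Aggregation**: the tested statistic is the across-pair average (one
  number per condition).  Each surrogate replicate draws one fresh
  surrogate per pair and re-averages, so the null replicates the observed
  statistic's averaging structure exactly.
* **P-values**: add-one estimator,
  `p = (1 + #{surrogate ≥ observed}) / (1 + n_surrogates)` one-tailed;
  two-tailed p = `min(1, 2·min(upper, lower))`.  The floor is
  `1/(n_surrogates+1)`; p = 0 is impossible.  Reported quantiles: 95% for
  one-tailed statistics, (2.5%, 97.5%) for two-tailed ones.
* **Defaults**: 20,000 surrogates for production analyses; the test suite
  and acceptance script use 500–1,000 (p-floor 1/1001 ≈ 0.001, ample for
  5%-level decisions) to stay within desk-scale compute.

Calibration is verified empirically: on uncoupled dyads the one-tailed TE
test rejects at 5.0% ± 2% (200 meta-replicates), and two-tailed p-values on
exchangeable data pass a KS test against uniformity.

## Cross-correlation and leader–follower inference

Pearson correlation recomputed on the overlapping support at every integer-
frame lag in ±`max_lag` (default 1 s) — no zero-padding, so short windows
carry no edge bias.  Positive lag means the first (small) series precedes.
Ties between lags resolve to the smallest |lag|, positive first, making the
scan deterministic.

The per-pair leader–follower statistic is **window-averaged**: correlation
maximum and signed lag per non-overlapping 20-s window, averaged over the
session (30 windows per 10-minute session), then averaged across pairs.
This is a deliberate design choice: under the rotation null, the argmax lag
of a single whole-session scan is nearly uniform over ±1 s, so the null
standard deviation of a 12-pair mean lag (~0.17 s) would swamp leads of a
few hundredths of a second; averaging over 30 windows × 12 pairs shrinks
it to ~0.04 s, which is what makes a 0.1-s lead statistically resolvable —
and is consistent with analyses that summarize sessions by ~30 windowed
similarity indices.  `window=None` restores the whole-session scan.

## Similarity index (replica fidelity)

Per non-overlapping 20-s window, the X and Y coordinate series of subject
and replica are lag-scanned (±1 s); the similarity index is the **minimum**
of the two channel maxima — the conservative choice, requiring both
coordinates to match (`combine="mean"` is available) — and the reported lag
is that of the binding channel.  A window succeeds when similarity ≥ 0.95
and |lag| ≤ 0.2 s.  Windows with < 90% of frames tracked in either series,
or with zero variance (a frozen subject), are invalid; `coverage_fraction`
is the fraction of valid windows.

## Proximity metrics

Inter-individual distance is the per-frame Euclidean distance on a common
clock.  Heading alignment is the dyad polarization
`|e^{iθ_a} + e^{iθ_b}|/2 = |cos((θ_a−θ_b)/2)|`, averaged within distance
bins (default: 5 equal-width bins up to the arena diagonal; empty bins are
NaN, never 0).  For independent uniform headings the expected polarization
is 2/π ≈ 0.637, the baseline against which "alignment in close proximity"
is read.  These are generic ethology conventions (proximity threshold
default: two small-subject body lengths, 6 cm), intended as standard
shoaling/schooling summaries rather than a reproduction of any particular
study's supplementary definitions.

## Synthetic generator

`simulate_dyad` emulates the study design the analysis targets: two
subjects in a 90 × 90 cm arena, 10-minute sessions, 30 Hz, 12 pairs per
condition, a small leader with a large follower (~33% body-length
difference, metadata only).

* **Leader**: Ornstein–Uhlenbeck speed (mean 8 cm/s ≈ 2.5 body lengths/s
  for a small adult, reversion 1.5 /s, diffusion 6 cm/s per √s), heading
  diffusion (1.8 rad/√s), soft wall avoidance (steer toward the arena
  centre with gain 4 /s inside a 12-cm margin), reflecting walls.
* **Follower**: identical own dynamics, plus per-frame blending of its
  speed and heading toward the leader's realized values τ seconds earlier
  with weight c (`coupling_strength`), plus a saturating attraction steer
  toward the leader's lagged position (`attraction_gain`, default 0.8 /s).
  Coupling acts on the *velocity* channels — exactly the channels the
  analysis reads — so c and τ are sharply recoverable: at c = 0.6,
  τ = 0.1 s the speed-lag estimate lands on +0.100 s (one 10-Hz frame) and
  net TE ≈ +0.3 bits.  Setting c = 0 *and* attraction to 0 yields two
  statistically independent swimmers (the configuration used for all null
  calibrations).
* **Relay channel** (`teleport_channel`): the replica samples the input
  trajectory `delay` (± per-frame Gaussian jitter) seconds in the past,
  adds Gaussian positional noise, and drops a Bernoulli fraction of frames
  (NaN).  Channel noise uses its own RNG stream so it can be toggled
  without changing the dyad underneath.
* **Symbol-chain oracle** (`simulate_coupled_chain`): X i.i.d. uniform on 4
  symbols, `Y[t+1] = X[t]` with probability c, else uniform.  Its exact TE
  is `log₂4 + p·log₂p + 3q·log₂q` with `p = c + (1−c)/4`, `q = (1−c)/4` —
  0 bits at c = 0, 2 bits at c = 1 — giving the estimator an analytic
  ground truth.

All generators are bit-reproducible from (config, seed); subjects use
separate child streams of the seed so follower-parameter changes leave the
leader's path untouched.

**What the generator does not emulate** — and therefore what passing tests
do *not* show about real recordings: body undulation and posture, visual
occlusions and identity swaps, burst-and-coast speed profiles,
wall-following behavior, non-stationary arousal drifts, and 3-D motion.
The generator establishes that the *estimators and tests* behave correctly
(calibration, power, parameter recovery) under known coupling; it cannot
validate biological conclusions.

## Problem sizes in the test suite and acceptance script

Chosen so the whole chain runs comfortably on one CPU while keeping every
statistical check meaningful:

* Chain-oracle checks: n = 50,000 (estimator accuracy), n = 600 (equality
  with the brute-force enumeration, machine precision).
* Type-I calibration: 200 meta-replicates × 12 uncoupled pairs × 60-s
  sessions at 10 Hz × 1,000 surrogates.  The rejection rate of a calibrated
  test is 5% at any session length; short sessions keep the 2.4 million
  surrogate TE evaluations fast.
* Parameter recovery: 20 studies × 12 pairs × 600-s sessions at 10 Hz ×
  500 surrogates, coupled (c = 0.6, τ = 0.1 s) and uncoupled.  Full-length
  sessions are kept here because lag resolution genuinely needs the 30
  windows per session (see the leader–follower section).
* 10 Hz rather than 30 Hz throughout the simulations: τ = 0.1 s is exactly
  one frame, making lag recovery a sharp, interpretable test; tripling the
  frame rate triples compute without changing any conclusion.

## Known limitations

* The plug-in TE estimator is biased upward at finite n; only
  surrogate-relative statements (p-values, quantile exceedances) are
  bias-robust.  Absolute TE values should not be compared across sessions
  of different lengths.
* History length k > 2 over a 4-letter alphabet (4^(2k+1) cells) is
  undersampled on 10-minute sessions; the implementation allows it but the
  `low_n` flag should be heeded.
* The similarity index is translation-invariant but not rotation-invariant
  across the pair of coordinate channels (X is compared with X, Y with Y),
  matching how a replica mirrors a subject in a fixed arena frame.
* Circular rotation assumes approximate stationarity within a session;
  strongly non-stationary sessions (e.g., habituation trends) make the
  null conservative.
* `leader_follower_summary` tests the mean lag; bimodal leadership
  (subjects alternating roles) would average toward zero and go undetected.
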