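# Methods note

This note records the mathematical definitions implemented in `warpelast`
and the rationale for every choice the headline results depend on.

## 1. Alignment: dynamic time warping

For series `x` (length N) and `y` (length M), the local cost is the absolute
difference `d(i, j) = |x_i − y_j|` and the cumulative cost satisfies

```
D[i, j] = d(i, j) + min(D[i−1, j], D[i, j−1], D[i−1, j−1])
```

with the usual boundary conditions, restricted to a Sakoe–Chiba band
`|i − j| ≤ band_radius`.  The optimal path is recovered by backtracking
from `(N−1, M−1)`; ties are broken diagonal → vertical → horizontal, which
keeps paths maximally diagonal and makes results deterministic.  A band
narrower than `|N − M|` is infeasible and raises.  The DP and backtracking
kernels are numba-compiled; a plain-recursion exhaustive oracle (no DP, no
memoization) is kept in the test suite and the two are checked for
cost-equality on thousands of random small problems.

Absolute difference (rather than squared) is used as the local cost because
the series are z-scored to unit variance and an L1 cost is less dominated
by the few largest excursions; with z-scored inputs the two choices give
nearly identical paths in practice.

## 2. Warp deviation and warp elasticity

A warping path is generally many-to-one in both directions, so it is
collapsed onto one series' clock: for each reference index `i` the warp
deviation is

```
WD(i) = i − mean{ j : (i, j) on the path }
```

WD is positive where the reference runs ahead of its matched partner
content.  For equal-length pairs the partner's deviation is defined as the
exact negation of the reference's (`WD_y = −WD_x`): the two series disagree
about a common clock by a single signed offset, and defining the partner
track by negation keeps the antisymmetry exact rather than approximate.
For unequal lengths the collapse is computed directly on the partner clock.

**Warp elasticity** is the first time-derivative of the smoothed deviation:

```
WE(t) = d/dt [ moving_average(WD, w) ](t)
```

implemented as a centered moving average (edge-replicated) followed by
`numpy.gradient` (central differences, one-sided at the ends).  WE is a
dimensionless rate — samples of drift per sample of time — so a segment of
the reference whose partner rendition is compressed from 30 to 20 samples
has true WE = (30 − 20)/30 = +1/3 throughout the segment.  Multiplying by
TR expresses drift in seconds per second of scan when desired.

Smoothing default: `w = max(3, band_radius // 4)`.  The deviation track is
integer-valued with unit steps; differentiating it raw yields a spike
train.  A window of a quarter of the band is long enough to suppress path
jitter but much shorter than the slowest in-band period, so piecewise
structure at the validation scale survives.  The default was fixed from
this reasoning before any ensemble evaluation and was not adjusted
afterwards.

Known edge behaviour: the path is pinned to `(0, 0)` and `(N−1, M−1)`, so
WD is anchored near zero at both ends and the first/last segments of a
piecewise design are attenuated relative to mid-series segments.  The
ensemble-mean magnitude of a mid-series ±1/3 segment is ≈ 0.2–0.3 (sign and
ordering always correct); smoothing trades exact plateau magnitude for
track stability.

## 3. Band-width rule

The warping band must span at least one cycle of the slowest oscillation
the data can contain, otherwise slow disagreements are truncated by the
band instead of being measured.  With sampling rate `fs` and a high-pass
cutoff `f3dB`, the minimum window is

```
n_window = round(0.88 · fs / f3dB) + 1
```

i.e. about 88 % of the slowest period, plus one sample for the centre.
This yields 123 samples at TR 0.72 s and 45 samples at TR 2 s for
`f3dB = 0.01 Hz`.  The band radius defaults to `n_window`.

## 4. Signal conditioning

Real time courses are conditioned per column: linear detrend → zero-phase
(forward–backward) order-4 Butterworth band-pass, 0.01–0.15 Hz by default →
z-score.  Zero-phase filtering is required because WE measures *timing*;
a causal filter's group delay would bias it.  Series shorter than three
times the filter's padding requirement are rejected rather than silently
filtered with dominant edge transients.

## 5. Synthetic validation designs

**Seven-segment stretch/shrink design** (`make_stretch_pair`): a 210-sample
Gaussian series is cut into seven 30-sample segments; the partner is each
segment FFT-resampled to 20, 40, 20, 30, 40, 20, 40 samples (factors 2/3,
4/3, 2/3, 1, 4/3, 2/3, 4/3) and re-concatenated — total 210 samples again.
Gaussian noise at 0.1 × signal SD is added to both members, then both are
band-passed (0.01–0.15 Hz) and z-scored.  The ground-truth elasticity on
the reference clock is piecewise-constant `1 − factor`.  The ensemble mean
of the estimate over 1000 pairs correlates with this truth at r ≈ 0.88.

**Two-phase comparison design** (`make_comparison_pair`): 400-sample pairs.
First half: *independent* band-limited unit-variance Gaussian noise in each
member — no coupling, elasticity truth 0, connectivity truth 0.  Second
half: a shared band-limited base cut into four 50-sample segments,
resampled by factors 0.6, 1.4, 0.6, 1.4 (to 30 + 70 + 30 + 70 = 200
samples) to form the partner — connectivity truth 1, elasticity truth
`1 − factor` per segment.  Every phase is band-limited and normalized to
unit variance *before* assembly.  This is deliberate: filtering the
concatenated series instead would (a) let the DTW path "pre-drift" through
the artificially smooth phase boundary, smearing deviation backwards into
the uncoupled half, and (b) leak narrow-band synchrony from the coupled
half into the first half, so phase synchrony would not track its zero truth
for reasons that have nothing to do with the estimators.  Per-phase
construction makes both truths exact by construction.  On 1000 pairs the
ensemble-mean WE correlates with the elasticity truth at r ≈ 0.92, while
every SWPC window and PS band tracks the connectivity truth at r ≤ 0.4 and
stays within |mean| < 0.05 of zero in the uncoupled half.

## 6. Noise model and tSNR

Noise injection targets a temporal SNR: `noise_SD = signal_level / tSNR`.
For raw fMRI the conventional signal level is the temporal mean, but the
simulated signals are z-scored and zero-mean, so the mean-based definition
is degenerate; the injector therefore uses the **RMS** as the signal level
for zero-mean inputs (RMS = SD = 1 after z-scoring, so `noise_SD = 1/tSNR`)
and refuses mean-mode on near-zero-mean series rather than dividing by ~0.

The sensitivity study uses 100 pairs × 15 log-spaced tSNR levels in
[0.01, 100].  Two summaries are reported per level:

* `r_ensemble` — correlation of the across-pair **mean** WE track with the
  truth.  This is the headline curve: single-pair tracks are dominated by
  path jitter at every noise level, so the estimator is an ensemble-level
  (or heavily averaged) readout, and this reading is consistent with the
  clean-data ensemble figure (≈ 0.88).
* `r_mean` / `r_std` — moments of the per-pair correlations, which plateau
  far lower (≈ 0.6) even without noise; reported for transparency.

The ensemble curve stays ≥ 0.71 for all tSNR ≥ 3.72 (measured ≈ 0.88) and
degrades below tSNR ≈ 2.

## 7. Baselines

* **SWPC**: centered sliding-window Pearson correlation; windows of 15, 45,
  75, 105, 135 s.  Window positions that overrun an edge, or contain a
  zero-variance member, are NaN (no padding, no imputation).
* **Phase synchrony**: zero-phase Butterworth band-pass to a narrow band
  (0.01–0.04 through 0.09–0.13 Hz), Hilbert analytic phase, and
  `cos(Δφ)`, which maps phase difference into [−1, 1] while preserving
  anticorrelation.
* Truth correlations use pairwise deletion of missing estimates.

## 8. WE states and group statistics

Pooled time points (subjects × time, one feature per unordered component
pair — the ordered matrix is antisymmetric, so half the columns are
redundant) are clustered with **k-medians**: L1 (city-block) assignment and
coordinatewise-median updates, L1 k-means++ seeding, 10 restarts, empty
clusters reseeded at the worst-fit point.  L1 geometry is chosen because WE
tracks have heavy-tailed excursions (path jumps); medians are robust to
them where means are not.  The implementation is self-contained because
widely available k-means implementations hard-code the L2
centroid/assignment pair.  Model order is guided by an elbow curve on the
within/between dispersion ratio.

Per-subject state dynamics: mean dwell time (× TR, NaN for unvisited
states), occupancy fraction, and a row-stochastic transition matrix (a
never-exited state gets self-probability 1).  Two-group comparison runs
Welch-free two-sample t-tests per metric, with Benjamini–Hochberg FDR
(via `scipy.stats.false_discovery_control`) applied *within each metric
family* (k dwell tests, k fraction tests, k² transition tests) — families
answer different questions and mixing them would let a strong effect in
one family mask or inflate discoveries in another.  Transition effects are
additionally summarized as a signed −log10(adjusted p) matrix.  Degenerate
cells (zero variance in both groups, or too few finite values) are skipped
with an explicit note instead of producing meaningless p-values.

## 9. Determinism and problem sizes

All randomness flows through explicit seeds (`numpy.random.SeedSequence`
spawning for independent streams), so every ensemble, fixture, and
clustering run is exactly reproducible.  Ensemble sizes (1000 pairs for the
validation and comparison studies, 100 × 15 for the noise study) were fixed
in advance as the smallest sizes at which the Monte-Carlo spread of the
reported correlations is well inside the stated ±0.05 tolerance, and run in
seconds-to-minutes on a single CPU.
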