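# warpelast

**Warp elasticity**: a time-resolved measure of how the coupling *timescale*
between two signals stretches and shrinks over time.

## The problem

Time-resolved functional connectivity between brain-network time courses is
usually summarized by how strongly two signals co-vary (sliding-window
correlation) or how tightly their phases lock (phase synchrony).  Both assume
the two signals evolve on a *common clock*.  But two coupled networks can
carry the same waveform while one plays it faster or slower than the other —
the coupling is intact, only its timescale is warped.  Amplitude- and
phase-based measures are blind to this dimension, and in the worst case
report a *drop* in connectivity exactly when the timescale warp is strongest.

`warpelast` quantifies that dimension directly:

1. **Align** the two series with dynamic time warping (DTW) under a
   Sakoe–Chiba band, giving an optimal monotone correspondence between their
   sample indices.
2. **Warp deviation (WD)**: collapse the warping path onto one series' clock
   and record, at each reference time point, how far ahead or behind the
   matched partner index runs.
3. **Warp elasticity (WE)**: the first time-derivative of the (smoothed)
   warp deviation.  WE is positive while the reference series is *stretched*
   relative to its partner (the partner plays the shared content faster),
   negative while it is *shrunk*, and zero when both run at the same rate.
   A 30-sample segment whose partner rendition occupies only 20 samples has
   ground-truth elasticity (30 − 20)/30 = **+0.33** on the reference clock.

The package also provides the surrounding machinery: a spectral rule for the
DTW band width, band-limited synthetic generators with known elasticity
ground truth, tSNR noise-sensitivity analysis, SWPC and phase-synchrony
baselines, k-medians clustering of pairwise elasticity into recurring
**WE states** with dwell/fraction/transition statistics and FDR-corrected
group comparison, and an end-to-end CLI pipeline for ICA network time
courses.

## Quick start

How wide should the warping band be?  The band must be wide enough to span
the slowest in-band cycle.  For fMRI filtered above 0.01 Hz:

```bash
$ warpelast window --tr 0.72
n_window = 123 samples (fs = 1.389 Hz, f3db = 0.01 Hz)
$ warpelast window --tr 2
n_window = 45 samples (fs = 0.5 Hz, f3db = 0.01 Hz)
```

## Worked example

Generate a synthetic pair whose ground truth is known: a 210-sample
band-limited (0.01–0.15 Hz) series cut into seven 30-sample segments, each
segment resampled in the partner to 20, 40, 20, 30, 40, 20, 40 samples.
On the reference clock the true elasticity is +1/3 on shrunk segments,
−1/3 on stretched ones, 0 on the unchanged one.

```python
import numpy as np
from warpelast import window_size, make_stretch_pair, elasticity_for_pair

band = window_size(1.0, 0.01).n_window      # 89 samples at TR = 1 s
x, y, truth = make_stretch_pair(seed=7)

es = elasticity_for_pair(x, y, band_radius=band)
print(round(float(np.corrcoef(es.values, truth)[0, 1]), 3))
# 0.478  -- a single noisy pair is dominated by path jitter
```

A single realization is noisy; the estimator is designed to be read at the
ensemble level.  Averaging 200 independent pairs:

```python
acc = np.zeros(truth.size)
for s in np.random.SeedSequence(7).spawn(200):
    xi, yi, _ = make_stretch_pair(seed=s)
    acc += elasticity_for_pair(xi, yi, band_radius=band).values
acc /= 200

print(round(float(np.corrcoef(acc, truth)[0, 1]), 3))   # 0.893
print(round(acc[65:85].mean(), 3))   # 0.237 on a mid-series 30->20 segment
print(round(acc[95:115].mean(), 3))  # 0.007 on the unchanged segment
```

The ensemble mean tracks the piecewise-constant truth (r = 0.893 at 200
pairs, ≈ 0.88 at 1000), recovers the sign and ordering of every segment,
and is near zero where nothing was warped.  (Interior magnitudes are
somewhat attenuated by smoothing and path-endpoint pinning; see
`docs/methods.md`.)

### Why not sliding-window correlation or phase synchrony?

On a two-phase benchmark — first half uncoupled noise, second half a shared
signal with four resampled segments — only WE tracks the elasticity truth
(100 pairs, `comparison_experiment(n_pairs=100, seed=7, band_radius=89)`):

```
method         config  r_ensemble
    WE band_radius=89       0.913
  SWPC            15s      -0.099
  SWPC            45s       0.072
  SWPC            75s       0.262
  SWPC           105s       0.355
  SWPC           135s       0.309
    PS    0.01-0.04Hz       0.241
    PS    0.03-0.07Hz      -0.007
    PS    0.05-0.09Hz       0.110
    PS    0.07-0.11Hz      -0.154
    PS    0.09-0.13Hz      -0.203
```

### Pipeline on real time courses

```bash
warpelast elasticity subj01.csv subj02.csv --tr 2 --out results/
warpelast states subj*.csv --tr 2 --k 4 --metadata groups.csv --out results/
```

Inputs are delimited matrices (rows = time, columns = components).  The
pipeline detrends, band-passes (0.01–0.15 Hz), z-scores, computes pairwise
WE for every ordered component pair, and optionally clusters the pooled
time points into k WE states with dwell-time/fraction/transition dynamics
and a BH-FDR-corrected two-group comparison.

## Testing and reproduction

```bash
python -m pytest -q tests/          # full suite, ~35 s on one CPU
```

`tests/test_acceptance.py` holds one test per headline validation claim;
the rest of the suite covers units and invariants (including a brute-force
DTW oracle).

Every headline number can be recomputed from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This regenerates, with all randomness derived from `--seed`: the 1000-pair
seven-segment ensemble correlation, the 1000-pair two-phase comparison
correlation, the worked stretch factor, both window-rule anchors, the
fixture length, and the tSNR noise-sensitivity lower bound (100 pairs × 15
log-spaced levels in [0.01, 100]).  Runtime ≈ 30 s on one CPU.
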