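"""Synthetic validation fixtures with known stretch/shrink ground truth.

Two generators mirror the method's validation studies:

* a seven-segment design: a 210-sample band-limited (0.01-0.15 Hz)
  random series whose 30-sample segments are resampled to
  20, 40, 20, 30, 40, 20, 40 samples to form its partner, giving a
  piecewise-constant ground-truth elasticity track;
* a two-phase comparison design: 400-sample pairs whose first half is
  independent Gaussian noise in both members (no coupling, elasticity 0)
  and whose second half is four 50-sample segments resampled by factors
  0.6, 1.4, 0.6, 1.4.

A tSNR-calibrated noise injector and a noise-sensitivity harness
complete the module.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .metrics import default_smoothing_window, elasticity_for_pair

__all__ = [
    "SegmentPlan",
    "FIG_PLAN",
    "bandlimited_noise",
    "make_stretch_pair",
    "make_comparison_pair",
    "inject_noise",
    "noise_sensitivity_curve",
    "tsnr_grid",
]

DEFAULT_BAND = (0.01, 0.15)  # Hz, the standard BOLD-relevant range


@dataclass(frozen=True)
class SegmentPlan:
    """Piecewise resampling plan: per-segment base lengths and factors.

    ``factors[k]`` is ``new_length / base_length`` for segment k of the
    partner series; the realized new length is ``round(factor * base)``.
    """

    base_lengths: tuple[int, ...]
    factors: tuple[float, ...]
    tr: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "base_lengths", tuple(int(b) for b in self.base_lengths))
        object.__setattr__(self, "factors", tuple(float(f) for f in self.factors))
        if len(self.base_lengths) != len(self.factors):
            raise ValueError("base_lengths and factors must have equal length")
        if any(f <= 0 for f in self.factors):
            raise ValueError("all factors must be > 0")
        if any(r < 2 for r in self.new_lengths):
            raise ValueError("every resampled segment must have length >= 2")

    @property
    def new_lengths(self) -> tuple[int, ...]:
        return tuple(int(round(f * b)) for f, b in zip(self.factors, self.base_lengths))

    @property
    def n_base(self) -> int:
        return sum(self.base_lengths)

    @property
    def n_new(self) -> int:
        return sum(self.new_lengths)

    def truth_track(self, reference: str = "x") -> np.ndarray:
        """Piecewise-constant ground-truth elasticity on the reference clock.

        With the un-resampled series as reference, a segment whose
        partner was resampled by factor s has truth ``1 - s`` -- the
        number of samples the reference is stretched relative to the
        partner, divided by the reference segment length (e.g. a 30->20
        segment gives (30-20)/30 = +0.33).  On the resampled series'
        clock the truth is ``1 - 1/s``.
        """
        pieces = []
        for base, new in zip(self.base_lengths, self.new_lengths):
            if reference == "x":
                pieces.append(np.full(base, (base - new) / base))
            else:
                pieces.append(np.full(new, (new - base) / new))
        return np.concatenate(pieces)


#: Seven 30-sample segments resampled to 20, 40, 20, 30, 40, 20, 40.
FIG_PLAN = SegmentPlan(
    base_lengths=(30,) * 7,
    factors=(2 / 3, 4 / 3, 2 / 3, 1.0, 4 / 3, 2 / 3, 4 / 3),
    tr=1.0,
)


def _bandpass_sos(band, fs, order: int = 4):
    lo, hi = band
    nyq = fs / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < Nyquist ({nyq} Hz)")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band=DEFAULT_BAND, tr: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    sos = _bandpass_sos(band, fs=1.0 / tr, order=order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def bandlimited_noise(
    n: int,
    tr: float = 1.0,
    band=DEFAULT_BAND,
    seed=None,
) -> np.ndarray:
    """Zero-phase band-passed Gaussian noise, unit variance after filtering."""
    rng = np.random.default_rng(seed)
    out = bandpass(rng.standard_normal(n), band=band, tr=tr)
    sd = out.std()
    if sd > 0:
        out = out / sd
    return out


def _resample_segments(base: np.ndarray, plan: SegmentPlan) -> np.ndarray:
    """FFT-resample each base segment to its planned new length."""
    pieces = []
    start = 0
    for blen, nlen in zip(plan.base_lengths, plan.new_lengths):
        seg = base[start : start + blen]
        pieces.append(seg if nlen == blen else signal.resample(seg, nlen))
        start += blen
    return np.concatenate(pieces)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def make_stretch_pair(
    plan: SegmentPlan = FIG_PLAN,
    seed=None,
    noise_sd: float = 0.1,
    band=DEFAULT_BAND,
):
    """Random pair with piecewise stretch/shrink structure and known truth.

    The reference series is a Gaussian random signal cut into the plan's
    base segments; the partner is each segment FFT-resampled to its
    planned length and re-concatenated.  Additive Gaussian noise
    (``noise_sd`` x signal SD) is injected into both members, which are
    then band-limited and z-scored.

    Returns
    -------
    (x, y, truth) : reference series, partner series, and the
        piecewise-constant ground-truth elasticity on the reference clock.
    """
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(plan.n_base)
    partner = _resample_segments(base, plan)
    x = base + noise_sd * base.std() * rng.standard_normal(base.size)
    y = partner + noise_sd * partner.std() * rng.standard_normal(partner.size)
    x = _zscore(bandpass(x, band=band, tr=plan.tr))
    y = _zscore(bandpass(y, band=band, tr=plan.tr))
    return x, y, plan.truth_track("x")


#: Resampling factors of the second-half segments of the comparison design.
COMPARISON_FACTORS = (0.6, 1.4, 0.6, 1.4)


def make_comparison_pair(seed=None, band=DEFAULT_BAND, tr: float = 1.0):
    """Two-phase 400-sample pair for the baseline comparison study.

    First half (200 samples): band-limited Gaussian noise generated
    independently in the two members -- connectivity truth 0, elasticity
    truth 0.  Second half: a band-limited random reference signal cut
    into four 50-sample segments, each resampled by factors
    0.6, 1.4, 0.6, 1.4 (to 30, 70, 30, 70 samples) to form the partner's
    second half -- connectivity truth 1 within the coupled span,
    elasticity truth ``1 - factor`` per segment.  Every phase is
    generated at unit variance and each member is z-scored.

    Each piece is band-limited *before* assembly (rather than filtering
    the concatenated series), so no alignment or synchrony structure
    leaks across the phase boundary by construction.

    Returns
    -------
    (x, y, elasticity_truth, connectivity_truth)
    """
    rng = np.random.default_rng(seed)
    n_half = 200
    plan = SegmentPlan(base_lengths=(50,) * 4, factors=COMPARISON_FACTORS, tr=tr)
    base = bandpass(rng.standard_normal(plan.n_base), band=band, tr=tr)
    base /= base.std()
    half_x = bandpass(rng.standard_normal(n_half), band=band, tr=tr)
    half_y = bandpass(rng.standard_normal(n_half), band=band, tr=tr)
    x = np.concatenate([half_x / half_x.std(), base])
    y = np.concatenate([half_y / half_y.std(), _resample_segments(base, plan)])
    elast_truth = np.concatenate([np.zeros(n_half), plan.truth_track("x")])
    conn_truth = np.concatenate([np.zeros(n_half), np.ones(plan.n_base)])
    return _zscore(x), _zscore(y), elast_truth, conn_truth


def inject_noise(series: np.ndarray, tsnr: float, seed=None, mean_mode: bool = False) -> np.ndarray:
    """Add zero-mean Gaussian noise realizing a target temporal SNR.

    The noise standard deviation is ``signal_level / tsnr`` where the
    signal level is the series mean in ``mean_mode`` (raw, un-z-scored
    fMRI convention) or the series RMS otherwise (appropriate for
    zero-mean simulated signals, whose mean would be ~0).
    """
    if not tsnr > 0:
        raise ValueError(f"tsnr must be > 0, got {tsnr}")
    series = np.asarray(series, dtype=np.float64)
    if mean_mode:
        level = series.mean()
        if abs(level) < 1e-12:
            raise ValueError(
                "series mean is ~0; the mean-based tSNR is undefined -- "
                "use the RMS mode (mean_mode=False) for zero-mean signals"
            )
        level = abs(level)
    else:
        level = float(np.sqrt(np.mean(series**2)))
    rng = np.random.default_rng(seed)
    return series + (level / tsnr) * rng.standard_normal(series.size)


def tsnr_grid(n: int = 15, lo: float = 0.01, hi: float = 100.0) -> np.ndarray:
    """Log-spaced tSNR grid, default 15 values spanning [0.01, 100]."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def noise_sensitivity_curve(
    tsnr_levels: np.ndarray | None = None,
    n_realizations: int = 100,
    seed=None,
    plan: SegmentPlan = FIG_PLAN,
    band_radius: int | None = None,
    smoothing_window: int | None = None,
    compare: str = "truth",
):
    """Truth-correlation of the elasticity estimate as a function of tSNR.

    For each of ``n_realizations`` stretch/shrink pairs and each tSNR
    level, zero-mean Gaussian noise (RMS-calibrated) is added to both
    members and warp elasticity is computed.  With ``compare='truth'``
    the estimates are correlated with the ground-truth track; with
    ``compare='clean'`` they are correlated with the elasticity of the
    same pair without injected noise (the convention for real data,
    where no ground truth exists).

    Returns
    -------
    summary : DataFrame indexed by tSNR with
        ``r_ensemble`` -- Pearson r of the across-realization mean
        elasticity track against the reference track, and
        ``r_mean`` / ``r_std`` -- moments of the per-realization
        correlations.  A single realization's track is dominated by
        warping-path noise, so ``r_ensemble`` is the headline curve.
    detail : tidy DataFrame, one row per (tsnr, realization).
    """
    if n_realizations < 2:
        raise ValueError("n_realizations must be >= 2")
    if compare not in ("truth", "clean"):
        raise ValueError(f"compare must be 'truth' or 'clean', got {compare!r}")
    if tsnr_levels is None:
        tsnr_levels = tsnr_grid()
    ss = np.random.SeedSequence(seed)
    pair_seeds, noise_root = ss.spawn(2)
    pairs = [make_stretch_pair(plan, seed=s) for s in pair_seeds.spawn(n_realizations)]
    if smoothing_window is None:
        smoothing_window = default_smoothing_window(band_radius)

    def estimate(a, b):
        return elasticity_for_pair(
            a, b, tr=plan.tr, band_radius=band_radius,
            smoothing_window=smoothing_window,
        ).values

    if compare == "clean":
        refs = [estimate(x, y) for x, y, _ in pairs]
    else:
        refs = [truth for _, _, truth in pairs]

    rows, summaries = [], []
    noise_seeds = noise_root.spawn(len(tsnr_levels) * n_realizations * 2)
    k = 0
    for tsnr in tsnr_levels:
        tracks = np.empty((n_realizations, refs[0].size))
        for idx, (x, y, _) in enumerate(pairs):
            xn = inject_noise(x, tsnr, seed=noise_seeds[k]); k += 1
            yn = inject_noise(y, tsnr, seed=noise_seeds[k]); k += 1
            tracks[idx] = estimate(xn, yn)
            rows.append({
                "tsnr": float(tsnr),
                "realization": idx,
                "r": _pearson(tracks[idx], refs[idx]),
            })
        ref_mean = np.mean(refs, axis=0)
        per_pair = [row["r"] for row in rows[-n_realizations:]]
        summaries.append({
            "tsnr": float(tsnr),
            "r_ensemble": _pearson(tracks.mean(axis=0), ref_mean),
            "r_mean": float(np.nanmean(per_pair)),
            "r_std": float(np.nanstd(per_pair)),
        })
    summary = pd.DataFrame(summaries).set_index("tsnr")
    return summary, pd.DataFrame(rows)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])
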