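"""Warp deviation, warp elasticity, and the spectral window-size rule.

Warp deviation collapses a DTW warping path into one signed value per
time point of a chosen reference series: how many samples the reference
lags (+) or leads (-) its partner at that moment.  Warp elasticity is
the temporal derivative of warp deviation -- a dimensionless
stretch (+) / shrink (-) factor of the reference's coupling timescale
relative to the partner.  Multiplying the factor by the sampling
interval expresses it in seconds of stretch per second, which makes
values comparable across acquisitions with different sampling rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .dtw import TimeSeriesPair, WarpPath, dtw

__all__ = [
    "WarpDeviationSeries",
    "ElasticitySeries",
    "WindowRule",
    "collapse_path",
    "warp_deviation",
    "warp_elasticity",
    "window_size",
    "pairwise_elasticity",
]


@dataclass(frozen=True)
class WarpDeviationSeries:
    """Per-timepoint signed deviation of a reference series vs its partner.

    ``values`` are in samples (one entry per reference index); positive
    means the reference lags / is delayed relative to the partner.
    ``values_seconds = values * tr``.
    """

    reference: str  # "x" or "y"
    values: np.ndarray
    tr: float = 1.0

    @property
    def values_seconds(self) -> np.ndarray:
        return self.values * self.tr


@dataclass(frozen=True)
class ElasticitySeries:
    """Dimensionless stretch/shrink factor per reference index.

    +0.5 means the reference's coupling timescale is stretching 50%
    relative to the partner; -0.5 means 50% shrinking; 0 means neither.
    ``values_scaled = values * tr`` expresses the factor as seconds of
    stretch per sample.
    """

    reference: str
    values: np.ndarray
    tr: float = 1.0
    smoothing_window: int = 1
    degenerate: bool = False  # flat (zero-variance) input; alignment arbitrary

    @property
    def values_scaled(self) -> np.ndarray:
        return self.values * self.tr


@dataclass(frozen=True)
class WindowRule:
    """Spectral rule linking the high-pass cutoff to a minimum DTW window.

    The warping-window length N satisfies ``f3db = 0.88 * Fs / (N - 1)``,
    so the minimum window at a given cutoff is
    ``N = round(0.88 * Fs / f3db) + 1`` samples.  At a 0.01 Hz high-pass
    this yields ~123 samples for a 0.72 s sampling interval and ~45 for
    a 2 s interval.
    """

    fs: float
    f3db: float
    n_window: int


def collapse_path(path: WarpPath, reference: str = "x") -> WarpDeviationSeries:
    """Collapse a (many-to-many) warping path to one deviation per index.

    For each index t of the reference series the matched partner indices
    are averaged, and the deviation is ``t - mean(partner indices)``.
    For equal-length pairs the deviation of ``y`` is defined as the exact
    negation of the deviation of ``x`` (both live on the same clock);
    for unequal lengths the collapse is carried out on the ``y`` side
    directly.
    """
    if reference not in ("x", "y"):
        raise ValueError(f"reference must be 'x' or 'y', got {reference!r}")
    i, j = path.i, path.j
    n, m = int(i[-1]) + 1, int(j[-1]) + 1
    if reference == "y" and n == m:
        return WarpDeviationSeries(reference="y", values=-_collapse(i, j, n))
    if reference == "x":
        return WarpDeviationSeries(reference="x", values=_collapse(i, j, n))
    return WarpDeviationSeries(reference="y", values=_collapse(j, i, m))


def _collapse(ref_idx: np.ndarray, other_idx: np.ndarray, n_ref: int) -> np.ndarray:
    counts = np.bincount(ref_idx, minlength=n_ref)
    sums = np.bincount(ref_idx, weights=other_idx, minlength=n_ref)
    return np.arange(n_ref, dtype=np.float64) - sums / counts


def warp_deviation(
    pair: TimeSeriesPair,
    band_radius: int | None = None,
    reference: str = "x",
) -> WarpDeviationSeries:
    """DTW then path collapse: signed per-timepoint deviation in samples."""
    path = dtw(pair, band_radius)
    dev = collapse_path(path, reference)
    return WarpDeviationSeries(reference=dev.reference, values=dev.values, tr=pair.tr)


def warp_elasticity(
    dev: WarpDeviationSeries,
    smoothing_window: int = 1,
) -> ElasticitySeries:
    """Temporal derivative of the (optionally smoothed) warp deviation.

    The raw deviation is a staircase (path steps are unit increments),
    so a centered moving average of width ``smoothing_window`` is applied
    before the centered first difference; ``smoothing_window <= 1``
    disables smoothing.

    Returns a dimensionless factor series; multiply by ``tr`` (see
    :attr:`ElasticitySeries.values_scaled`) for seconds.
    """
    values = np.asarray(dev.values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("deviation series must have length >= 2")
    smoothing_window = int(smoothing_window)
    if smoothing_window > values.size:
        raise ValueError(
            f"smoothing_window={smoothing_window} exceeds series length {values.size}"
        )
    if smoothing_window > 1:
        smooth = uniform_filter1d(values, size=smoothing_window, mode="nearest")
    else:
        smooth = values
    elast = np.gradient(smooth)
    return ElasticitySeries(
        reference=dev.reference,
        values=elast,
        tr=dev.tr,
        smoothing_window=max(smoothing_window, 1),
    )


def default_smoothing_window(band_radius: int | None) -> int:
    """Default pre-derivative smoother width: band_radius / 4, at least 3."""
    if band_radius is None:
        return 3
    return max(3, int(band_radius) // 4)


def window_size(fs: float, f3db: float) -> WindowRule:
    """Minimum DTW window length from the sampling rate and high-pass cutoff.

    ``n = round(0.88 * fs / f3db) + 1`` samples; requires ``fs > 2*f3db > 0``.
    """
    if not (f3db > 0 and fs > 2 * f3db):
        raise ValueError(f"require fs > 2*f3db > 0, got fs={fs}, f3db={f3db}")
    n = int(round(0.88 * fs / f3db)) + 1
    return WindowRule(fs=fs, f3db=f3db, n_window=n)


def elasticity_for_pair(
    x: np.ndarray,
    y: np.ndarray,
    tr: float = 1.0,
    band_radius: int | None = None,
    smoothing_window: int | None = None,
    reference: str = "x",
) -> ElasticitySeries:
    """Convenience: DTW -> deviation -> elasticity for one pair of series.

    Flat (zero-variance) members make the alignment arbitrary; the
    elasticity is then returned as all zeros with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if smoothing_window is None:
        smoothing_window = default_smoothing_window(band_radius)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        n = x.size if reference == "x" else y.size
        return ElasticitySeries(
            reference=reference,
            values=np.zeros(n),
            tr=tr,
            smoothing_window=smoothing_window,
            degenerate=True,
        )
    pair = TimeSeriesPair(x=x, y=y, tr=tr)
    dev = warp_deviation(pair, band_radius, reference)
    return warp_elasticity(dev, smoothing_window)


def pairwise_elasticity(
    tc: np.ndarray,
    tr: float = 1.0,
    band_radius: int | None = None,
    smoothing_window: int | None = None,
    labels: list[str] | None = None,
):
    """Elasticity for every ordered component pair of a time-course matrix.

    Parameters
    ----------
    tc : ndarray, shape (T, C)
        One column per component, equal-length.
    labels : optional list of C component names.

    Returns
    -------
    elasticity : ndarray, shape (T, C*(C-1)) for the ordered pairs
    pairs : list of (a, b) label tuples in the same column order

    The unordered pair is computed once with the first member as
    reference; the reversed ordering is its exact negation, so the
    component-by-component matrix view is antisymmetric.
    """
    tc = np.asarray(tc, dtype=np.float64)
    if tc.ndim != 2 or tc.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 components")
    t, c = tc.shape
    if labels is None:
        labels = [f"c{k}" for k in range(c)]
    if len(labels) != c:
        raise ValueError("labels length must match component count")
    cols: dict[tuple[int, int], np.ndarray] = {}
    for a, b in itertools.combinations(range(c), 2):
        es = elasticity_for_pair(
            tc[:, a], tc[:, b], tr=tr, band_radius=band_radius,
            smoothing_window=smoothing_window,
        )
        cols[(a, b)] = es.values
        cols[(b, a)] = -es.values
    pairs = [(a, b) for a, b in itertools.permutations(range(c), 2)]
    out = np.column_stack([cols[p] for p in pairs])
    pair_labels = [(labels[a], labels[b]) for a, b in pairs]
    return out, pair_labels
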