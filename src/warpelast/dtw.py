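"""Windowed dynamic time warping with Euclidean local cost.

The alignment core: pointwise local-distance matrix, cumulative-cost
dynamic program under an optional Sakoe-Chiba band, and backtracking of
the optimal warping path.  Paths from this module are the raw material
for warp deviation and warp elasticity.

Conventions
-----------
* Indices are 0-based.  The path starts at ``(0, 0)`` and ends at
  ``(N-1, M-1)``.
* The band constraint is ``|i - j| <= band_radius``; ``band_radius=None``
  means unconstrained.
* Ties in the recurrence minimum are broken preferring the diagonal
  predecessor, then the vertical ``(i-1, j)``, then the horizontal
  ``(i, j-1)``.  This is deterministic and biases toward one-to-one
  matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "TimeSeriesPair",
    "CostMatrices",
    "WarpPath",
    "BandInfeasibleError",
    "local_distance_matrix",
    "accumulate",
    "backtrack",
    "dtw",
]


class BandInfeasibleError(ValueError):
    """The Sakoe-Chiba band is too narrow to connect the two corners."""


@dataclass(frozen=True)
class TimeSeriesPair:
    """Two real-valued series sharing a sampling interval.

    Parameters
    ----------
    x, y : array-like
        1-D series of length >= 2 each.  Lengths may differ.
    tr : float
        Sampling interval in seconds (> 0), identical for both members.
    """

    x: np.ndarray
    y: np.ndarray
    tr: float = 1.0

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.float64).ravel()
        y = np.asarray(self.y, dtype=np.float64).ravel()
        for name, arr in (("x", x), ("y", y)):
            if arr.size < 2:
                raise ValueError(f"series {name!r} must have length >= 2, got {arr.size}")
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"series {name!r} has non-finite value at index {bad[0]}"
                )
        if not (np.isfinite(self.tr) and self.tr > 0):
            raise ValueError(f"tr must be a positive number, got {self.tr!r}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def m(self) -> int:
        return self.y.size


@dataclass
class CostMatrices:
    """Local and cumulative DTW cost matrices.

    ``local[i, j] = |x[i] - y[j]|`` (Euclidean distance for scalars);
    ``cumulative`` holds the accumulated minimal cost, ``inf`` outside
    the band.  ``band_radius=None`` means unbounded.
    """

    local: np.ndarray
    band_radius: int | None = None
    cumulative: np.ndarray | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.local.shape


@dataclass(frozen=True)
class WarpPath:
    """Optimal warping path: ordered (i, j) index pairs plus total cost."""

    pairs: np.ndarray  # (L, 2) int array
    cost: float

    def __post_init__(self):
        pairs = np.asarray(self.pairs, dtype=np.intp)
        object.__setattr__(self, "pairs", pairs)

    @property
    def i(self) -> np.ndarray:
        """Indices on the x side."""
        return self.pairs[:, 0]

    @property
    def j(self) -> np.ndarray:
        """Indices on the y side."""
        return self.pairs[:, 1]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.pairs, fmt="%d", delimiter=",", header="i,j", comments="")


def local_distance_matrix(pair: TimeSeriesPair, band_radius: int | None = None) -> CostMatrices:
    """Pointwise Euclidean distance matrix ``|x[i] - y[j]|``.

    The band radius is recorded but not applied to the values; it takes
    effect in :func:`accumulate`.
    """
    local = np.abs(pair.x[:, None] - pair.y[None, :])
    return CostMatrices(local=local, band_radius=_check_band(band_radius))


def _check_band(band_radius):
    if band_radius is None:
        return None
    band_radius = int(band_radius)
    if band_radius < 1:
        raise ValueError(f"band_radius must be >= 1 or None, got {band_radius}")
    return band_radius


@njit(cache=False)
def _accumulate_kernel(local, band):  # pragma: no cover - numba
    n, m = local.shape
    d = np.full((n, m), np.inf)
    d[0, 0] = local[0, 0]
    for i in range(n):
        if band < 0:
            jlo, jhi = 0, m
        else:
            jlo = max(0, i - band)
            jhi = min(m, i + band + 1)
        for j in range(jlo, jhi):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0 and d[i - 1, j - 1] < best:
                best = d[i - 1, j - 1]
            if i > 0 and d[i - 1, j] < best:
                best = d[i - 1, j]
            if j > 0 and d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = local[i, j] + best
    return d


@njit(cache=False)
def _backtrack_kernel(d):  # pragma: no cover - numba
    n, m = d.shape
    maxlen = n + m - 1
    path = np.empty((maxlen, 2), dtype=np.intp)
    i, j = n - 1, m - 1
    k = maxlen - 1
    path[k, 0] = i
    path[k, 1] = j
    while i > 0 or j > 0:
        # tie preference: diagonal, then vertical, then horizontal
        if i > 0 and j > 0:
            best = d[i - 1, j - 1]
            move = 0
            if d[i - 1, j] < best:
                best = d[i - 1, j]
                move = 1
            if d[i, j - 1] < best:
                move = 2
        elif i > 0:
            move = 1
        else:
            move = 2
        if move == 0:
            i -= 1
            j -= 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
        k -= 1
        path[k, 0] = i
        path[k, 1] = j
    return path[k:]


def accumulate(cost: CostMatrices, band_radius: int | None = None) -> CostMatrices:
    """Fill the cumulative-cost matrix by the DTW recurrence.

    ``D[i, j] = local[i, j] + min(D[i-1, j], D[i, j-1], D[i-1, j-1])``
    over in-band cells; out-of-band cells stay infinite.

    Raises
    ------
    BandInfeasibleError
        If ``|N - M| > band_radius`` so no admissible path reaches the
        terminal corner.
    """
    if band_radius is None:
        band_radius = cost.band_radius
    band_radius = _check_band(band_radius)
    n, m = cost.shape
    if band_radius is not None and abs(n - m) > band_radius:
        raise BandInfeasibleError(
            f"band_radius={band_radius} cannot connect corners of a {n}x{m} "
            f"alignment (length difference {abs(n - m)})"
        )
    band = -1 if band_radius is None else band_radius
    cumulative = _accumulate_kernel(np.ascontiguousarray(cost.local), band)
    return CostMatrices(local=cost.local, band_radius=band_radius, cumulative=cumulative)


def backtrack(cost: CostMatrices) -> WarpPath:
    """Trace the optimal path from the terminal corner back to (0, 0)."""
    if cost.cumulative is None:
        raise ValueError("cumulative matrix not filled; call accumulate() first")
    d = cost.cumulative
    terminal = d[-1, -1]
    if not np.isfinite(terminal):
        raise BandInfeasibleError("terminal corner unreachable; widen the band")
    pairs = _backtrack_kernel(d)
    return WarpPath(pairs=pairs, cost=float(terminal))


def dtw(pair: TimeSeriesPair, band_radius: int | None = None) -> WarpPath:
    """Full DTW: local distances, cumulative DP, backtracking.

    Parameters
    ----------
    pair : TimeSeriesPair
    band_radius : int or None
        Sakoe-Chiba band half-width in samples; ``None`` for no
        constraint.

    Returns
    -------
    WarpPath
        Optimal path with boundary pairs ``(0, 0)`` and ``(N-1, M-1)``
        and the accumulated distance cost.
    """
    cost = local_distance_matrix(pair, band_radius)
    cost = accumulate(cost)
    return backtrack(cost)
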