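"""Warp-elasticity states: L1 k-means clustering and state dynamics.

Time-resolved pairwise-elasticity vectors (one per subject and time
point) are pooled and clustered with k-means under the city-block (L1)
distance; the natural centroid update under L1 assignment is the
coordinatewise median (k-medians).  Each cluster centroid is a recurring
whole-brain stretching/shrinking pattern ("WE state").  Per-subject
state sequences are then summarised by mean dwell time, fraction rate,
and a row-stochastic transition matrix, and the summaries are compared
between groups with two-sample t-tests under Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "StateModel",
    "StateDynamics",
    "GroupComparison",
    "cluster_states",
    "elbow_curve",
    "state_dynamics",
    "group_compare",
]


@dataclass
class StateModel:
    """Fitted k-medians model over pooled elasticity vectors."""

    k: int
    centroids: np.ndarray  # (k, d)
    labels: np.ndarray  # pooled observation labels, 0-based
    inertia: float  # total city-block distance to assigned centroids
    n_iter: int = 0

    def assignments(self, n_subjects: int, n_time: int) -> np.ndarray:
        """Reshape pooled labels to (subjects, time)."""
        return self.labels.reshape(n_subjects, n_time)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmin(cdist(np.atleast_2d(X), self.centroids, "cityblock"), axis=1)


@dataclass
class StateDynamics:
    """Per-subject state-dynamics summaries.

    mean_dwell : (subjects, k) seconds; NaN for states never visited.
    fraction : (subjects, k) occupancy in [0, 1], rows sum to 1.
    transition : (subjects, k, k) row-stochastic; self-transitions count,
        and a state never exited keeps self-probability 1 by convention.
    """

    mean_dwell: np.ndarray
    fraction: np.ndarray
    transition: np.ndarray
    tr: float = 1.0

    @property
    def k(self) -> int:
        return self.fraction.shape[1]


@dataclass
class GroupComparison:
    """Two-sample t-tests on state dynamics with BH-FDR adjustment."""

    table: pd.DataFrame  # metric, state, t, p, p_adj, significant
    alpha: float = 0.05
    signed_logp_transition: np.ndarray | None = field(default=None)


def _assign(X, centroids):
    d = cdist(X, centroids, "cityblock")
    labels = np.argmin(d, axis=1)
    return labels, d[np.arange(X.shape[0]), labels].sum()


def _fit_once(X, k, rng, max_iter=300):
    # k-means++-style seeding under the L1 metric
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    closest = cdist(X, centroids[:1], "cityblock").ravel()
    for c in range(1, k):
        p = closest / closest.sum() if closest.sum() > 0 else np.full(n, 1 / n)
        centroids[c] = X[rng.choice(n, p=p)]
        closest = np.minimum(closest, cdist(X, centroids[c : c + 1], "cityblock").ravel())
    labels = None
    for it in range(max_iter):
        new_labels, inertia = _assign(X, centroids)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if members.size:
                centroids[c] = np.median(members, axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                far = np.argmax(cdist(X, centroids, "cityblock").min(axis=1))
                centroids[c] = X[far]
    labels, inertia = _assign(X, centroids)
    return centroids, labels, inertia, it + 1


def cluster_states(
    X: np.ndarray,
    k: int,
    n_init: int = 10,
    seed=None,
    max_iter: int = 300,
) -> StateModel:
    """City-block k-means (k-medians) over pooled elasticity vectors.

    Parameters
    ----------
    X : ndarray, shape (n_obs, d)
        Pooled observations: all subjects' time points stacked.  A 3-D
        (subjects, time, d) array is flattened over the first two axes.
    k : int
        Number of states (>= 1); the best of ``n_init`` restarts by
        total L1 inertia is kept.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X.reshape(-1, X.shape[-1])
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_obs, d) or 3-D (subjects, time, d)")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k={k} must be in [1, n_obs={X.shape[0]}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centroids, labels, inertia, n_iter = _fit_once(X, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia, n_iter)
    centroids, labels, inertia, n_iter = best
    return StateModel(k=k, centroids=centroids, labels=labels,
                      inertia=float(inertia), n_iter=n_iter)


def elbow_curve(X: np.ndarray, k_range, n_init: int = 10, seed=None) -> pd.DataFrame:
    """WSS/BSS ratio (squared Euclidean) per candidate k.

    Assignment uses the city-block model; the within- and
    between-cluster sums of squares are evaluated with squared Euclidean
    distances.  The curve is a diagnostic -- no automatic k selection.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X.reshape(-1, X.shape[-1])
    grand = X.mean(axis=0)
    rows = []
    ss = np.random.SeedSequence(seed)
    for k, sub in zip(k_range, ss.spawn(len(list(k_range)))):
        model = cluster_states(X, k, n_init=n_init, seed=sub)
        wss = bss = 0.0
        for c in range(k):
            members = X[model.labels == c]
            if members.size == 0:
                continue
            wss += ((members - model.centroids[c]) ** 2).sum()
            bss += members.shape[0] * ((model.centroids[c] - grand) ** 2).sum()
        rows.append({"k": k, "wss": wss, "bss": bss,
                     "ratio": wss / bss if bss > 0 else np.inf})
    return pd.DataFrame(rows)


def state_dynamics(assignments: np.ndarray, k: int, tr: float = 1.0) -> StateDynamics:
    """Dwell times, fraction rates, and transition matrices per subject.

    ``assignments`` is (subjects, time) of 0-based state labels.  Mean
    dwell time is the average contiguous-run length of a state (runs
    truncated by scan edges included) times ``tr``.  Transitions count
    consecutive time-point label pairs including self-transitions; rows
    of states never occupied before the final time point get
    self-probability 1.
    """
    assignments = np.atleast_2d(np.asarray(assignments))
    n_sub, n_time = assignments.shape
    mean_dwell = np.full((n_sub, k), np.nan)
    fraction = np.zeros((n_sub, k))
    transition = np.zeros((n_sub, k, k))
    for s in range(n_sub):
        seq = assignments[s]
        counts = np.bincount(seq, minlength=k)
        fraction[s] = counts / n_time
        # contiguous runs
        change = np.flatnonzero(np.diff(seq)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n_time]])
        for a, b in zip(starts, ends):
            c = seq[a]
            run = (b - a) * tr
            mean_dwell[s, c] = run if np.isnan(mean_dwell[s, c]) else mean_dwell[s, c] + run
        n_runs = np.zeros(k)
        for a in starts:
            n_runs[seq[a]] += 1
        with np.errstate(invalid="ignore"):
            mean_dwell[s] = mean_dwell[s] / np.where(n_runs > 0, n_runs, np.nan)
        # transition counts
        np.add.at(transition[s], (seq[:-1], seq[1:]), 1)
        row_sums = transition[s].sum(axis=1)
        for c in range(k):
            if row_sums[c] > 0:
                transition[s, c] /= row_sums[c]
            else:
                transition[s, c, c] = 1.0
    return StateDynamics(mean_dwell=mean_dwell, fraction=fraction,
                         transition=transition, tr=tr)


def _bh(p: np.ndarray) -> np.ndarray:
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan, dtype=np.float64)
    if ok.any():
        adj[ok] = stats.false_discovery_control(p[ok], method="bh")
    return adj


def group_compare(dyn_a: StateDynamics, dyn_b: StateDynamics, alpha: float = 0.05) -> GroupComparison:
    """Two-sample t-tests on dwell, fraction, and transition metrics.

    BH-FDR adjustment is applied within each metric family separately
    (k dwell tests, k fraction tests, k*k transition tests).  Metrics
    with zero pooled variance are skipped (p = NaN, flagged in the
    table).  For transitions a signed ``-log10(p_adj)`` matrix is
    returned: the sign of the group-A-minus-group-B mean difference
    times the -log10 adjusted p-value.
    """
    if dyn_a.k != dyn_b.k:
        raise ValueError("state counts differ between groups")
    k = dyn_a.k
    if dyn_a.fraction.shape[0] < 2 or dyn_b.fraction.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []

    def run_family(name, a_vals, b_vals, labels):
        pvals, tvals, diffs, notes = [], [], [], []
        for col in range(a_vals.shape[1]):
            a = a_vals[:, col]
            b = b_vals[:, col]
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
                tvals.append(np.nan)
                pvals.append(np.nan)
                diffs.append(np.nan)
                notes.append("skipped: degenerate or insufficient data")
                continue
            t, p = stats.ttest_ind(a, b)
            tvals.append(float(t))
            pvals.append(float(p))
            diffs.append(float(a.mean() - b.mean()))
            notes.append("")
        padj = _bh(np.array(pvals))
        for lab, t, p, pa, d, note in zip(labels, tvals, pvals, padj, diffs, notes):
            rows.append({
                "metric": name, "state": lab, "t": t, "p": p, "p_adj": pa,
                "mean_diff": d,
                "significant": bool(np.isfinite(pa) and pa < alpha),
                "note": note,
            })
        return padj, np.array(diffs)

    run_family("mean_dwell", dyn_a.mean_dwell, dyn_b.mean_dwell,
               [str(c + 1) for c in range(k)])
    run_family("fraction", dyn_a.fraction, dyn_b.fraction,
               [str(c + 1) for c in range(k)])
    ta = dyn_a.transition.reshape(dyn_a.transition.shape[0], -1)
    tb = dyn_b.transition.reshape(dyn_b.transition.shape[0], -1)
    labels = [f"{i + 1}->{j + 1}" for i in range(k) for j in range(k)]
    padj, diffs = run_family("transition", ta, tb, labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        signed = np.sign(diffs) * -np.log10(padj)
    return GroupComparison(
        table=pd.DataFrame(rows),
        alpha=alpha,
        signed_logp_transition=signed.reshape(k, k),
    )
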