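"""Signal conditioning, file I/O, and the end-to-end elasticity pipeline.

Inputs are delimited-text matrices of component (ICA network) time
courses: a header row of component labels, one row per time point, plus
a known sampling interval (TR).  Conditioning follows the standard
post-ICA sequence: per-column linear detrend, zero-phase Butterworth
band-pass (0.01-0.15 Hz by default), z-score.  The pipeline then
computes pairwise warp elasticity per subject and, optionally, WE
states, dynamics, and group statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import __version__
from .metrics import default_smoothing_window, pairwise_elasticity, window_size
from .states import cluster_states, group_compare, state_dynamics

__all__ = [
    "ConditioningConfig",
    "RunConfig",
    "read_timecourses",
    "write_timecourses",
    "condition",
    "run_pipeline",
]


@dataclass(frozen=True)
class ConditioningConfig:
    """Post-ICA conditioning: detrend -> zero-phase band-pass -> z-score."""

    band: tuple[float, float] = (0.01, 0.15)
    filter_order: int = 4
    detrend: bool = True
    zscore: bool = True


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    ``band_radius`` and ``smoothing_window`` default to the spectral
    window rule (at the conditioning band's low edge) and a quarter of
    the band radius, respectively.
    """

    tr: float
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "warpelast_out"
    band_radius: int | None = None
    smoothing_window: int | None = None
    k: int | None = None
    n_init: int = 10
    seed: int = 0
    groups: dict[str, str] = field(default_factory=dict)  # subject id -> group
    conditioning: ConditioningConfig = field(default_factory=ConditioningConfig)

    def resolved(self) -> "RunConfig":
        band_radius = self.band_radius
        if band_radius is None:
            band_radius = window_size(1.0 / self.tr, self.conditioning.band[0]).n_window
        smoothing = self.smoothing_window
        if smoothing is None:
            smoothing = default_smoothing_window(band_radius)
        out = RunConfig(**{**asdict(self), "conditioning": self.conditioning})
        out.band_radius = band_radius
        out.smoothing_window = smoothing
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditioning"]["band"] = list(self.conditioning.band)
        return d

    def digest(self) -> str:
        """Hash of the analysis parameters (not input/output locations)."""
        d = self.to_dict()
        d.pop("inputs", None)
        d.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def read_timecourses(path) -> tuple[np.ndarray, list[str]]:
    """Read a delimited time-course matrix (rows = time, cols = components).

    The delimiter is taken from the extension (``.tsv`` -> tab, else
    comma).  Comment lines starting with ``#`` are ignored.  Ragged rows,
    non-numeric cells, and missing values raise a parse error naming the
    offending line.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text: {exc}") from exc
    labels = [str(c) for c in df.columns]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: missing or non-numeric value in column {labels[c]!r} "
            f"at data line {r + 2}"  # +1 header, +1 1-based
        )
    return values, labels


def write_timecourses(path, matrix: np.ndarray, labels: list[str], header: str | None = None):
    """Write a time-course matrix as CSV, optionally with a provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(np.asarray(matrix), columns=labels).to_csv(fh, index=False)


def condition(matrix: np.ndarray, tr: float, cfg: ConditioningConfig = ConditioningConfig()) -> np.ndarray:
    """Per-column detrend -> zero-phase band-pass -> z-score.

    The filter is a Butterworth band-pass applied forward-backward
    (zero phase).  Series shorter than the filter's padding requirement
    are rejected with a pointer to a lower filter order.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D (time x components) matrix")
    fs = 1.0 / tr
    lo, hi = cfg.band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {cfg.band} must lie inside (0, Nyquist={fs / 2} Hz)")
    out = matrix.copy()
    if cfg.detrend:
        out = signal.detrend(out, axis=0, type="linear")
    sos = signal.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if out.shape[0] <= 3 * padlen:
        raise ValueError(
            f"series length {out.shape[0]} too short for an order-"
            f"{cfg.filter_order} zero-phase filter (needs > {3 * padlen} "
            "samples); use a lower filter order"
        )
    out = signal.sosfiltfilt(sos, out, axis=0)
    if cfg.zscore:
        sd = out.std(axis=0)
        sd[sd == 0] = 1.0
        out = (out - out.mean(axis=0)) / sd
    return out


def _long_format(elast: np.ndarray, pair_labels, tr: float, subject: str) -> pd.DataFrame:
    t, _ = elast.shape
    frames = []
    time_s = np.arange(t) * tr
    for col, (a, b) in enumerate(pair_labels):
        frames.append(pd.DataFrame({
            "subject": subject,
            "time_s": time_s,
            "comp_a": a,
            "comp_b": b,
            "elasticity": elast[:, col],
            "elasticity_seconds": elast[:, col] * tr,
        }))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Condition inputs, compute pairwise elasticity, optional states.

    Each input file is one subject.  Outputs (written under
    ``cfg.output_dir``): a resolved-config JSON, per-subject long-format
    elasticity CSVs, and -- when ``cfg.k`` is set -- centroids,
    assignments, dynamics, and (with >= 2 groups in ``cfg.groups``) a
    group-comparison table.

    Returns a dict with the in-memory results.
    """
    if not cfg.inputs:
        raise ValueError("no input files given")
    cfg = cfg.resolved()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = f"warpelast {__version__} config {cfg.digest()}"
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
    subjects, tensors = [], []
    pair_labels = None
    for path in cfg.inputs:
        name = Path(path).stem
        matrix, labels = read_timecourses(path)
        conditioned = condition(matrix, cfg.tr, cfg.conditioning)
        elast, pair_labels = pairwise_elasticity(
            conditioned, tr=cfg.tr, band_radius=cfg.band_radius,
            smoothing_window=cfg.smoothing_window, labels=labels,
        )
        subjects.append(name)
        tensors.append(elast)
        long = _long_format(elast, pair_labels, cfg.tr, name)
        with open(outdir / f"elasticity_{name}.csv", "w") as fh:
            fh.write(f"# {provenance}\n")
            long.to_csv(fh, index=False)
    tensor = np.stack(tensors)  # subjects x time x ordered-pairs

    results: dict = {
        "config": cfg,
        "subjects": subjects,
        "pair_labels": pair_labels,
        "tensor": tensor,
    }
    if cfg.k is not None:
        # cluster on the unordered half to avoid doubling antisymmetric columns
        keep = [idx for idx, (a, b) in enumerate(pair_labels) if a < b]
        pooled = tensor[:, :, keep].reshape(-1, len(keep))
        model = cluster_states(pooled, cfg.k, n_init=cfg.n_init, seed=cfg.seed)
        assignments = model.assignments(len(subjects), tensor.shape[1])
        dyn = state_dynamics(assignments, cfg.k, tr=cfg.tr)
        results.update(model=model, assignments=assignments, dynamics=dyn)
        pd.DataFrame(
            model.centroids,
            columns=[f"{pair_labels[idx][0]}|{pair_labels[idx][1]}" for idx in keep],
        ).to_csv(outdir / "centroids.csv", index=False)
        pd.DataFrame(assignments, index=subjects).to_csv(outdir / "assignments.csv")
        dyn_rows = []
        for s, name in enumerate(subjects):
            for c in range(cfg.k):
                dyn_rows.append({
                    "subject": name, "state": c + 1,
                    "mean_dwell_s": dyn.mean_dwell[s, c],
                    "fraction": dyn.fraction[s, c],
                })
        pd.DataFrame(dyn_rows).to_csv(outdir / "dynamics.csv", index=False)
        groups = {s: g for s, g in cfg.groups.items() if s in subjects}
        names = sorted(set(groups.values()))
        if len(names) == 2:
            idx_a = [s for s, n in enumerate(subjects) if groups.get(n) == names[0]]
            idx_b = [s for s, n in enumerate(subjects) if groups.get(n) == names[1]]
            dyn_a = state_dynamics(assignments[idx_a], cfg.k, tr=cfg.tr)
            dyn_b = state_dynamics(assignments[idx_b], cfg.k, tr=cfg.tr)
            comparison = group_compare(dyn_a, dyn_b)
            results["comparison"] = comparison
            (outdir / "group_comparison.json").write_text(
                json.dumps({
                    "groups": names,
                    "alpha": comparison.alpha,
                    "tests": comparison.table.to_dict(orient="records"),
                }, indent=2, default=float)
            )
    return results
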