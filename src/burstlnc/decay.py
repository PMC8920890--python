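"""RNA decay: control-gene normalization and exponential half-life fitting.

A transcription-shutoff (actinomycin D) time course gives each gene a decay
series. Library-size distortions at individual time points are corrected with
control genes of known half-life: the expected control level at time t is
exp(-k_control * t), and the median observed/expected ratio over controls is
the normalization factor for that time point and sample. Per-gene decay is
then fitted as y = a * exp(-k t) by nonlinear least squares.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit",
    "normalize_to_t0",
    "normalization_factor",
    "apply_control_normalization",
    "fit_decay",
    "fit_decay_table",
    "parse_timepoint_columns",
]


@dataclass
class DecayFit:
    gene: str
    amplitude: float
    rate: float  # per hour
    residual: float
    converged: bool

    @property
    def half_life(self) -> float:
        """t1/2 = ln 2 / k; the identity t1/2 * k = ln 2 holds exactly."""
        return math.log(2.0) / self.rate if self.rate > 0 else math.inf

    def passes(self, *, max_half_life: float = 10.0) -> bool:
        return self.converged and self.rate > 0 and self.half_life < max_half_life


_COL_RE = re.compile(r"^t(?P<time>[0-9.]+)_r(?P<rep>\d+)$")


def parse_timepoint_columns(columns) -> pd.DataFrame:
    """Parse ``t{hours}_r{replicate}`` column labels into (time, replicate)."""
    rows = []
    for c in columns:
        m = _COL_RE.match(str(c))
        if not m:
            raise ValueError(f"column {c!r} does not match 't<time>_r<rep>'")
        rows.append((c, float(m["time"]), int(m["rep"])))
    return pd.DataFrame(rows, columns=["column", "time", "replicate"]).set_index("column")


def normalize_to_t0(expr: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's series by its own t = 0 value, per replicate.

    Genes with a zero t0 value in any replicate are dropped with a warning.
    Idempotent: applying twice changes nothing.
    """
    meta = parse_timepoint_columns(expr.columns)
    out = expr.astype(float).copy()
    reps = sorted(meta["replicate"].unique())
    dropped = pd.Index([])
    for rep in reps:
        cols = meta.index[meta["replicate"] == rep]
        t0_col = meta.loc[cols].sort_values("time").index[0]
        if meta.at[t0_col, "time"] != 0.0:
            raise ValueError(f"replicate {rep} lacks a t=0 column")
        t0 = out[t0_col]
        dropped = dropped.union(out.index[t0 <= 0])
        out[cols] = out[cols].div(t0, axis=0)
    if len(dropped):
        warnings.warn(f"dropped {len(dropped)} gene(s) with zero t0 value", stacklevel=2)
        out = out.drop(index=dropped)
    return out


def normalization_factor(relative: pd.DataFrame, controls: pd.DataFrame, time: float,
                         column: str, *, late_exclude_half_life: float = 2.0,
                         late_time_points=(7.0, 10.0), min_controls: int = 3) -> float:
    """Median observed/expected ratio over control genes at one time point.

    ``controls`` has columns gene_id and half_life (hours, each in (1, 8)).
    At the late time points (7 h and 10 h by default) controls with
    half-lives below 2 h are excluded — their expected levels are too close
    to zero to calibrate against.
    """
    ctrl = controls.copy()
    ctrl = ctrl[(ctrl["half_life"] > 1.0) & (ctrl["half_life"] < 8.0)]
    if any(abs(time - lt) < 1e-9 for lt in late_time_points):
        ctrl = ctrl[ctrl["half_life"] >= late_exclude_half_life]
    ctrl = ctrl[ctrl["gene_id"].isin(relative.index)]
    if len(ctrl) < min_controls:
        raise ValueError(
            f"only {len(ctrl)} eligible control genes at t={time} (need >= {min_controls})"
        )
    k = math.log(2.0) / ctrl["half_life"].to_numpy()
    expected = np.exp(-k * time)
    observed = relative.loc[ctrl["gene_id"], column].to_numpy(dtype=float)
    return float(np.median(observed / expected))


def apply_control_normalization(relative: pd.DataFrame, controls: pd.DataFrame,
                                **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide every column by its control-gene normalization factor.

    Returns the corrected table and a table of the factors used.
    """
    meta = parse_timepoint_columns(relative.columns)
    out = relative.copy()
    rows = []
    for col in relative.columns:
        t = meta.at[col, "time"]
        if t == 0.0:
            f = 1.0
        else:
            f = normalization_factor(relative, controls, t, col, **kwargs)
        out[col] = relative[col] / f
        rows.append((col, t, f))
    return out, pd.DataFrame(rows, columns=["column", "time", "factor"])


def fit_decay(series, times, *, gene: str = "", max_half_life: float = 10.0) -> DecayFit:
    """Fit y = a * exp(-k t) by nonlinear least squares in original space.

    Initialized from the log-linear regression slope on positive values, so
    the fit is robust to amplitudes away from 1. A non-positive or
    vanishing rate fails the half-life gate (t1/2 >= ``max_half_life``).
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) != len(t) or len(y) < 3:
        raise ValueError("need >= 3 time points")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 1e-6)
        a0 = math.exp(intercept)
    else:
        k0, a0 = 0.1, max(y.max(), 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tt, a, k: a * np.exp(-k * tt), t, y,
                p0=(a0, k0), bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
            )
        a, k = float(popt[0]), float(popt[1])
        resid = float(np.sum((y - a * np.exp(-k * t)) ** 2))
        converged = True
    except RuntimeError:
        a, k, resid, converged = float("nan"), float("nan"), float("inf"), False
    return DecayFit(gene=gene, amplitude=a, rate=k, residual=resid, converged=converged)


def fit_decay_table(normalized: pd.DataFrame, *, max_half_life: float = 10.0) -> pd.DataFrame:
    """Fit every gene in a normalized time-course table.

    Replicates enter the least squares jointly (each column is one
    observation at its time). Returns a table with amplitude, rate,
    half_life and the pass flag.
    """
    meta = parse_timepoint_columns(normalized.columns)
    times = meta["time"].to_numpy()
    rows = []
    for gid, series in normalized.iterrows():
        f = fit_decay(series.to_numpy(dtype=float), times, gene=gid,
                      max_half_life=max_half_life)
        rows.append((gid, f.amplitude, f.rate, f.half_life, f.residual,
                     f.passes(max_half_life=max_half_life)))
    return pd.DataFrame(
        rows, columns=["gene_id", "amplitude", "rate", "half_life", "residual", "pass"]
    ).set_index("gene_id")
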