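"""Evoked-potential analysis: condition averages, the prediction-error
potential (PE-LFP), and the time-resolved prediction-error index.

The PE-LFP is the difference of the deviant and control condition-averaged
local field potentials.  Its significance profile is a per-time-point
paired t-test across recording sites (each site's trace is itself a
trial average, hence approximately normal), corrected over the tested
time points either by Benjamini-Hochberg FDR (default, q = 0.1) or by
Bonferroni; maximal significant runs are reported as intervals.

The time-resolved index recomputes the baseline-corrected spike count in
12 consecutive 20-ms windows tiling [−50, 190] ms, re-normalizes the
(DEV, STD, CTR) triplet per window, and tests the per-window index against
zero with a signed-rank test under FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import response as rq
from .indices import decompose
from .stats import bh_fdr, signed_rank_test

__all__ = [
    "PELFPResult",
    "average_lfp",
    "pe_lfp",
    "significant_intervals",
    "default_windows",
    "windowed_triplet",
    "time_resolved_ipe",
]


@dataclass
class PELFPResult:
    """Difference wave with its pointwise significance profile."""

    time_ms: np.ndarray
    difference: np.ndarray  # grand-average DEV − CTR
    p_values: np.ndarray
    mask: np.ndarray
    intervals: list[tuple[float, float]]
    correction: str


def average_lfp(traces: np.ndarray) -> np.ndarray:
    """Pointwise mean over trials/sites (rows of a 2-D array)."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 1:
        raise ValueError("traces must be a non-empty (n, time) array")
    return traces.mean(axis=0)


def pe_lfp(
    dev: np.ndarray,
    ctr: np.ndarray,
    time_ms: np.ndarray,
    correction: str = "fdr",
    q: float = 0.1,
    alpha: float = 0.05,
) -> PELFPResult:
    """Prediction-error potential across matched recording sites.

    ``dev`` and ``ctr`` are (n_sites, n_time) arrays of site-averaged
    traces.  The grand-average difference wave is tested at every time
    point with a two-tailed paired t-test across sites.
    """
    dev, ctr = np.asarray(dev, dtype=float), np.asarray(ctr, dtype=float)
    if dev.shape != ctr.shape:
        raise ValueError("DEV and CTR site sets must match")
    if dev.ndim != 2 or dev.shape[0] < 2:
        raise ValueError("need at least two sites")
    time_ms = np.asarray(time_ms, dtype=float)
    if time_ms.size != dev.shape[1]:
        raise ValueError("time vector must match the traces")

    diff = dev.mean(axis=0) - ctr.mean(axis=0)
    t, p = sps.ttest_rel(dev, ctr, axis=0)
    p = np.nan_to_num(p, nan=1.0)
    if correction == "fdr":
        mask, _ = bh_fdr(p, q=q)
    elif correction == "bonferroni":
        mask = p < alpha / p.size
    elif correction == "none":
        mask = p < alpha
    else:
        raise ValueError("correction must be 'fdr', 'bonferroni' or 'none'")
    return PELFPResult(
        time_ms=time_ms,
        difference=diff,
        p_values=p,
        mask=mask,
        intervals=significant_intervals(mask, time_ms),
        correction=correction,
    )


def significant_intervals(
    mask: np.ndarray, time_ms: np.ndarray
) -> list[tuple[float, float]]:
    """Maximal runs of the significance mask as (onset, offset) ms pairs.

    The union of the returned intervals covers exactly the masked samples
    (lossless run-length encoding).
    """
    mask = np.asarray(mask, dtype=bool)
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((float(time_ms[start]), float(time_ms[i - 1])))
            start = None
    if start is not None:
        out.append((float(time_ms[start]), float(time_ms[mask.size - 1])))
    return out


def default_windows(
    start_ms: float = -50.0, width_ms: float = 20.0, n_windows: int = 12
) -> list[tuple[float, float]]:
    """Twelve consecutive 20-ms windows tiling [−50, 190] ms."""
    return [
        (start_ms + k * width_ms, start_ms + (k + 1) * width_ms)
        for k in range(n_windows)
    ]


def windowed_triplet(
    dev_raster: rq.TrialRaster,
    std_raster: rq.TrialRaster,
    ctr_raster: rq.TrialRaster,
    window: tuple[float, float],
) -> tuple[float, float, float]:
    """(DEV, STD, CTR) baseline-corrected spike counts restricted to one
    window.

    The baseline stays the pre-onset estimate of each raster regardless of
    the window, so windows differ only in where the positive area is
    integrated.
    """
    out = []
    for r in (dev_raster, std_raster, ctr_raster):
        base = rq.baseline_rate(r)
        sdf = rq.spike_density(r)
        out.append(rq.bcsc(sdf, base, window=window))
    return tuple(out)


def time_resolved_ipe(
    points: list[tuple[rq.TrialRaster, rq.TrialRaster, rq.TrialRaster]],
    windows: list[tuple[float, float]] | None = None,
    q: float = 0.1,
) -> pd.DataFrame:
    """Per-window prediction-error index across a set of neuron/tone points.

    For every window the triplet is recomputed, renormalized, and the index
    tested against zero (signed-rank across points) with FDR control over
    the windows.  Returns one row per window with mean, SEM, p, and the
    corrected significance flag.
    """
    if windows is None:
        windows = default_windows()
    lo, hi = rq.WINDOW_MS
    for a, b in windows:
        if a < lo or b > hi:
            raise ValueError(f"window ({a}, {b}) outside raster coverage")
    if not points:
        raise ValueError("need at least one neuron/tone point")
    rows = []
    per_window_vals: list[np.ndarray] = []
    for w in windows:
        vals = []
        for dev_r, std_r, ctr_r in points:
            d, s, c = windowed_triplet(dev_r, std_r, ctr_r, w)
            idx = decompose((d, s, c))
            if idx.defined:
                vals.append(idx.ipe)
        per_window_vals.append(np.asarray(vals))
    p_raw = []
    for vals in per_window_vals:
        if vals.size >= 2 and np.any(vals != 0):
            _, p = signed_rank_test(vals)
        else:
            p = 1.0
        p_raw.append(p)
    signif, p_adj = bh_fdr(np.asarray(p_raw), q=q)
    for (a, b), vals, p, padj, sig in zip(
        windows, per_window_vals, p_raw, p_adj, signif
    ):
        n = vals.size
        rows.append(
            {
                "window_start_ms": a,
                "window_end_ms": b,
                "n_points": n,
                "mean_ipe": float(vals.mean()) if n else float("nan"),
                "sem_ipe": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "p_value": p,
                "p_adjusted": padj,
                "significant": bool(sig),
            }
        )
    return pd.DataFrame(rows)
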