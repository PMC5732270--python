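"""Spike-response quantification: spike-density functions, the
baseline-corrected spike count (BCSC), and its Monte-Carlo significance.

The response measure mirrors the standard oddball-analysis chain: per-trial
spike times aligned to tone onset over [−75, 250] ms are histogrammed in
1-ms steps, smoothed with a 6-ms Gaussian kernel into a spike-density
function (SDF, in Hz), and the excitatory response is the area of the SDF
above the spontaneous baseline rate (estimated from the 75 ms before onset)
over 0–180 ms after onset, keeping positive patches only.  Significance is
assessed against a Monte-Carlo null of constant-rate Poisson spiking pushed
through the identical chain; p = (g + 1) / (N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "WINDOW_MS",
    "RESPONSE_WINDOW_MS",
    "KERNEL_SD_MS",
    "TrialRaster",
    "SDF",
    "ResponseMeasure",
    "select_std_trials",
    "average_std",
    "spike_density",
    "baseline_rate",
    "bcsc",
    "pooled_baseline_rate",
    "monte_carlo_significance",
    "measure_response",
    "inclusion_filter",
    "compute_fra",
    "FRAResult",
]

#: analysis window around tone onset, ms
WINDOW_MS = (-75.0, 250.0)
#: excitatory-response integration window, ms
RESPONSE_WINDOW_MS = (0.0, 180.0)
#: Gaussian smoothing kernel SD, ms
KERNEL_SD_MS = 6.0
BIN_MS = 1.0
BASELINE_DUR_S = 0.075

_N_BINS = int(round((WINDOW_MS[1] - WINDOW_MS[0]) / BIN_MS))
_EDGES = WINDOW_MS[0] + BIN_MS * np.arange(_N_BINS + 1)
_CENTERS = _EDGES[:-1] + BIN_MS / 2.0
_PRE = _CENTERS < 0.0


@dataclass
class TrialRaster:
    """Per-trial spike times (ms, onset-aligned) for one neuron and role.

    ``positions`` optionally records the 0-based sequence position of each
    trial and ``is_deviant`` whether that position held a deviant; both are
    needed to select the last-standard-before-deviant trials of an oddball.
    ``tone_indices`` carries the per-trial grid tone for full-sequence
    rasters whose tone varies from trial to trial (``tone_index`` is then
    None).
    """

    trials: list[np.ndarray]
    neuron_id: str | int | None = None
    station: str | None = None
    condition: str | None = None
    tone_index: int | None = None
    window_ms: tuple[float, float] = WINDOW_MS
    positions: np.ndarray | None = None
    is_deviant: np.ndarray | None = None
    tone_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        lo, hi = self.window_ms
        for t in self.trials:
            if t.size and (t.min() < lo or t.max() > hi):
                raise ValueError("spike time outside the raster window")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts(self) -> np.ndarray:
        """Spike counts per 1-ms bin summed over trials."""
        out = np.zeros(_N_BINS)
        for t in self.trials:
            out += np.histogram(t, bins=_EDGES)[0]
        return out


@dataclass
class SDF:
    """Trial-averaged spike-density function on a 1-ms grid."""

    time_ms: np.ndarray
    rate_hz: np.ndarray
    kernel_sd_ms: float = KERNEL_SD_MS

    def area_spikes(self, window: tuple[float, float] | None = None) -> float:
        """Integral of the SDF (in spikes/trial) over ``window``."""
        m = np.ones_like(self.time_ms, dtype=bool)
        if window is not None:
            m = (self.time_ms > window[0]) & (self.time_ms < window[1])
        return float(np.sum(self.rate_hz[m]) * BIN_MS / 1000.0)


@dataclass
class ResponseMeasure:
    """Baseline-corrected spike count with its Monte-Carlo p-value."""

    bcsc: float
    baseline_rate_hz: float
    p_value: float
    n_null: int = 1000
    n_trials: int = 0
    flags: tuple[str, ...] = ()


def select_std_trials(raster: TrialRaster) -> TrialRaster:
    """Keep only the standard trial immediately preceding each deviant.

    Responses to the standard stabilize after many repetitions; using the
    last standard before each deviant matches the adaptation state probed by
    the deviant and equalizes trial counts across conditions.
    """
    if raster.positions is None or raster.is_deviant is None:
        raise ValueError("raster needs positions and deviant flags")
    pos = np.asarray(raster.positions)
    dev = np.asarray(raster.is_deviant, dtype=bool)
    wanted = pos[dev] - 1
    lookup = {int(p): i for i, p in enumerate(pos)}
    idx = [lookup[int(w)] for w in wanted if int(w) in lookup and not dev[lookup[int(w)]]]
    tones = raster.tone_indices
    return replace(
        raster,
        trials=[raster.trials[i] for i in idx],
        condition="STD",
        positions=pos[idx],
        is_deviant=dev[idx],
        tone_indices=tones[idx] if tones is not None else None,
    )


def spike_density(raster: TrialRaster, kernel_sd_ms: float = KERNEL_SD_MS) -> SDF:
    """Smooth the trial-averaged peri-stimulus histogram into an SDF (Hz).

    The kernel is truncated at the window edges without renormalization, so
    a small fraction of mass leaks out for spikes within a few SDs of an
    edge.
    """
    if raster.n_trials == 0:
        raise ValueError("empty raster")
    rate = raster.counts() / (raster.n_trials * BIN_MS / 1000.0)
    smoothed = gaussian_filter1d(rate, sigma=kernel_sd_ms / BIN_MS, mode="constant")
    return SDF(time_ms=_CENTERS.copy(), rate_hz=smoothed, kernel_sd_ms=kernel_sd_ms)


def baseline_rate(raster: TrialRaster) -> float:
    """Spontaneous rate (Hz): pre-onset spikes / (n_trials × 75 ms)."""
    if raster.n_trials == 0:
        return 0.0
    pre = float(raster.counts()[_PRE].sum())
    return pre / (raster.n_trials * BASELINE_DUR_S)


def pooled_baseline_rate(rasters) -> float:
    """Spontaneous rate (Hz) pooled over the pre-onset windows of several
    rasters.

    The spontaneous rate is a property of the neuron, so the Monte-Carlo
    null model uses this pooled estimate (all trials of all sequences)
    rather than the 40-trial per-condition estimate, which is too noisy to
    serve as a plug-in rate.
    """
    spikes = 0.0
    trials = 0
    for r in rasters:
        spikes += float(r.counts()[_PRE].sum())
        trials += r.n_trials
    if trials == 0:
        return 0.0
    return spikes / (trials * BASELINE_DUR_S)


def bcsc(
    sdf: SDF,
    baseline_rate_hz: float,
    window: tuple[float, float] = RESPONSE_WINDOW_MS,
) -> float:
    """Positive area of the SDF above baseline over ``window``, in spikes.

    Suppression below baseline is ignored (positive patches only), so the
    measure is non-negative and targets excitatory responses.
    """
    m = (sdf.time_ms > window[0]) & (sdf.time_ms < window[1])
    excess = np.clip(sdf.rate_hz[m] - baseline_rate_hz, 0.0, None)
    return float(excess.sum() * BIN_MS / 1000.0)


def _chain_from_counts(
    counts: np.ndarray,
    n_trials: int,
    kernel_sd_ms: float = KERNEL_SD_MS,
    window: tuple[float, float] = RESPONSE_WINDOW_MS,
) -> np.ndarray:
    """BCSC for each row of a (n_rep, n_bins) summed-count matrix.

    Reproduces baseline estimation, smoothing, and positive-area integration
    exactly as the observed-data path does.
    """
    counts = np.atleast_2d(counts)
    base = counts[:, _PRE].sum(axis=1) / (n_trials * BASELINE_DUR_S)
    rate = counts / (n_trials * BIN_MS / 1000.0)
    sm = gaussian_filter1d(rate, sigma=kernel_sd_ms / BIN_MS, axis=1, mode="constant")
    m = (_CENTERS > window[0]) & (_CENTERS < window[1])
    excess = np.clip(sm[:, m] - base[:, None], 0.0, None)
    return excess.sum(axis=1) * BIN_MS / 1000.0


def monte_carlo_significance(
    observed_bcsc: float,
    baseline_rate_hz: float,
    n_trials: int,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    kernel_sd_ms: float = KERNEL_SD_MS,
    window: tuple[float, float] = RESPONSE_WINDOW_MS,
) -> float:
    """Monte-Carlo p-value of a BCSC against constant-rate Poisson spiking.

    ``n_null`` peri-stimulus histograms are simulated at the spontaneous
    rate, each passed through the identical baseline → SDF → BCSC chain
    (including re-estimating its own baseline), and
    p = (g + 1) / (n_null + 1) with g the number of null measures ≥ the
    observed one.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = baseline_rate_hz * n_trials * BIN_MS / 1000.0
    null_counts = rng.poisson(lam, size=(n_null, _N_BINS))
    null_bcsc = _chain_from_counts(null_counts, n_trials, kernel_sd_ms, window)
    g = int(np.sum(null_bcsc >= observed_bcsc))
    return (g + 1) / (n_null + 1)


def measure_response(
    raster: TrialRaster,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    window: tuple[float, float] = RESPONSE_WINDOW_MS,
    null_rate_hz: float | None = None,
) -> ResponseMeasure:
    """Full chain on a raster: SDF, baseline, BCSC, Monte-Carlo p-value.

    ``null_rate_hz`` sets the constant rate of the Monte-Carlo null; when
    None the raster's own baseline is used.  Passing the neuron's pooled
    spontaneous rate (see :func:`pooled_baseline_rate`) stabilizes the
    null model when the raster has few trials.
    """
    base = baseline_rate(raster)
    sdf = spike_density(raster)
    observed = bcsc(sdf, base, window=window)
    p = monte_carlo_significance(
        observed,
        base if null_rate_hz is None else null_rate_hz,
        raster.n_trials,
        n_null=n_null,
        seed=seed,
        window=window,
    )
    return ResponseMeasure(
        bcsc=observed,
        baseline_rate_hz=base,
        p_value=p,
        n_null=n_null,
        n_trials=raster.n_trials,
    )


def average_std(
    asc: ResponseMeasure | None, desc: ResponseMeasure | None
) -> ResponseMeasure:
    """Average the standard-condition measure across oddball directions.

    If only one direction exists the available measure is passed through
    with a ``single_direction`` provenance flag.  The p-value of an averaged
    measure is the smaller of the two direction p-values (the tone counts as
    responsive if either direction shows a significant response).
    """
    if asc is None and desc is None:
        raise ValueError("at least one direction is required")
    if asc is None or desc is None:
        m = asc if asc is not None else desc
        return replace(m, flags=m.flags + ("single_direction",))
    return ResponseMeasure(
        bcsc=0.5 * (asc.bcsc + desc.bcsc),
        baseline_rate_hz=0.5 * (asc.baseline_rate_hz + desc.baseline_rate_hz),
        p_value=min(asc.p_value, desc.p_value),
        n_null=asc.n_null,
        n_trials=asc.n_trials + desc.n_trials,
    )


def inclusion_filter(
    dev: ResponseMeasure,
    std: ResponseMeasure,
    ctr: ResponseMeasure,
    alpha: float = 0.05,
) -> bool:
    """Keep a neuron/tone point iff at least one condition is significantly
    excitatory (min p ≤ alpha, boundary inclusive)."""
    for m in (dev, std, ctr):
        if m is None:
            raise ValueError("all three condition measures are required")
    return min(dev.p_value, std.p_value, ctr.p_value) <= alpha


@dataclass
class FRAResult:
    """Characteristic frequency and tuning sharpness from a
    frequency-response area."""

    cf_hz: float | None
    threshold_db: float | None
    q30: float | None
    untuned: bool
    fra: pd.DataFrame = field(repr=False, default=None)


def compute_fra(
    table: pd.DataFrame,
    alpha: float = 0.05,
    q_level_offset_db: float = 30.0,
) -> FRAResult:
    """Summarize a frequency × intensity response map.

    ``table`` needs columns ``freq_hz``, ``level_db``, ``bcsc``,
    ``p_value``.  The characteristic frequency (CF) is the frequency with a
    significant response at the lowest intensity (strongest response breaks
    ties); threshold is that intensity.  Q30 = CF / bandwidth of the
    contiguous significant frequency band containing the CF at threshold
    + 30 dB.  A fragmented significant region at that level, or no
    measurable bandwidth, yields the untuned flag.
    """
    required = {"freq_hz", "level_db", "bcsc", "p_value"}
    if not required.issubset(table.columns):
        raise ValueError(f"FRA table needs columns {sorted(required)}")
    levels = np.sort(table["level_db"].unique())
    if levels.size < 3:
        raise ValueError("FRA needs at least 3 intensity levels")
    sig = table[table["p_value"] <= alpha]
    if sig.empty:
        return FRAResult(None, None, None, True, table)
    threshold = float(sig["level_db"].min())
    at_thr = sig[sig["level_db"] == threshold]
    cf = float(at_thr.sort_values("bcsc", ascending=False)["freq_hz"].iloc[0])

    target = threshold + q_level_offset_db
    level = float(levels[np.argmin(np.abs(levels - target))])
    row = table[table["level_db"] == level].sort_values("freq_hz")
    sig_mask = (row["p_value"] <= alpha).to_numpy()
    freqs = row["freq_hz"].to_numpy()
    runs = _runs(sig_mask)
    cf_runs = [r for r in runs if freqs[r[0]] <= cf <= freqs[r[1]]]
    if len(runs) != 1 or not cf_runs:
        return FRAResult(cf, threshold, None, True, table)
    lo, hi = cf_runs[0]
    bw = freqs[hi] - freqs[lo]
    if bw <= 0:
        return FRAResult(cf, threshold, None, True, table)
    return FRAResult(cf, threshold, cf / bw, False, table)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out
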