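"""Spike-isolation quality metrics.

Three checks that a recorded spike set belongs to one well-isolated unit:

* **SNR** — peak-to-trough amplitude of the mean waveform divided by the
  pooled standard deviation of the residual samples (waveform minus mean);
  amplitude relative to background noise.
* **ISI violations** — fraction of inter-spike intervals shorter than the
  refractory period (4 ms by default).
* **Mahalanobis profile** — distance of every waveform to the set's mean
  under the set's covariance in waveform space.  A single Gaussian cluster
  has squared distances near the chi-square distribution with one degree
  of freedom per sample (median ≈ 31.3 for 32 samples); a mixture of units
  pushes the median above that reference, while tighter-than-Gaussian
  waveforms pull it below (left skew).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = [
    "WaveformSet",
    "MahalanobisProfile",
    "snr",
    "isi_violations",
    "mahalanobis_profile",
]

N_SAMPLES = 32  # samples per acquired waveform stream


@dataclass
class WaveformSet:
    """n × n_samples spike waveforms with their event times (ms)."""

    waveforms: np.ndarray
    spike_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if self.waveforms.shape[0] < 1:
            raise ValueError("need at least one waveform")
        if self.spike_times_ms is not None:
            self.spike_times_ms = np.asarray(self.spike_times_ms, dtype=float)


def snr(waveform_set: WaveformSet | np.ndarray) -> float:
    """Spike-amplitude-to-noise ratio of a waveform set.

    (max − min) of the mean waveform over the pooled SD of all residual
    samples.  Infinite when the residuals have zero variance.
    """
    w = _waves(waveform_set)
    if w.shape[0] < 2:
        raise ValueError("need at least two waveforms")
    mean = w.mean(axis=0)
    amplitude = float(mean.max() - mean.min())
    noise = float((w - mean).std(ddof=1))
    if noise <= 1e-12 * max(amplitude, 1.0):
        return float("inf")
    return amplitude / noise


def isi_violations(spike_times_ms, refractory_ms: float = 4.0) -> float:
    """Fraction of inter-spike intervals below the refractory period.

    Invariant under time translation and input ordering; NaN for fewer
    than two spikes.
    """
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    if t.size < 2:
        return float("nan")
    isi = np.diff(t)
    return float(np.mean(isi < refractory_ms))


@dataclass
class MahalanobisProfile:
    """Per-waveform distances against the single-Gaussian reference."""

    distances: np.ndarray
    median_sq: float
    reference_median_sq: float
    left_skewed: bool  # observed median below the single-Gaussian reference
    regularized: bool


def mahalanobis_profile(
    waveform_set: WaveformSet | np.ndarray,
    ridge: float | None = None,
) -> MahalanobisProfile:
    """Mahalanobis distance of each waveform to its own cluster.

    The covariance is the sample covariance of the set; when it is
    near-singular (n ≤ n_samples, or duplicated waveforms) a ridge of
    1e-6 × trace / n_samples is added to the diagonal.  Distances are
    compared against the chi-square reference for one Gaussian cluster.
    """
    w = _waves(waveform_set)
    n, d = w.shape
    if n < 2:
        raise ValueError("need at least two waveforms")
    mu = w.mean(axis=0)
    cov = np.cov(w, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    regularized = False
    eigmin = float(np.linalg.eigvalsh(cov).min())
    tiny = 1e-10 * max(float(np.trace(cov)) / d, 1e-30)
    if ridge is None and (n <= d or eigmin <= tiny):
        # scale the ridge to the data, not the (possibly zero) covariance
        scale = max(float(np.trace(cov)) / d, float(np.mean(w**2)), 1e-30)
        ridge = 1e-6 * scale
    if ridge:
        cov = cov + ridge * np.eye(d)
        regularized = True
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular covariance; pass a ridge value"
        ) from err
    y = np.linalg.solve(chol, (w - mu).T)
    d2 = np.sum(y**2, axis=0)
    ref = float(chi2.ppf(0.5, df=d))
    med = float(np.median(d2))
    return MahalanobisProfile(
        distances=np.sqrt(d2),
        median_sq=med,
        reference_median_sq=ref,
        left_skewed=med < ref,
        regularized=regularized,
    )


def _waves(waveform_set: WaveformSet | np.ndarray) -> np.ndarray:
    if isinstance(waveform_set, WaveformSet):
        return waveform_set.waveforms
    return np.atleast_2d(np.asarray(waveform_set, dtype=float))
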