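"""Fluctuation metrics of a trapped-segment trace.

The magnitude of the filtered-signal fluctuations carries the biophysics:
a flexible (apo) cage fluctuates more than a stiff, mineral-filled (holo)
one, and the 3-fold-channel gating during iron loading switches the
fluctuation amplitude between two levels.  This module measures those
fluctuations: a sliding-window RMS series, the normalized RMS (NRMS =
std / median level, comparable across nanostructures with different
transmission), a kernel-density PDF, quartile summaries, and the fraction
of spectral power in the low-frequency conformational band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .preprocess import kde_on_grid
from .trace import Trace

__all__ = ["RmsSeries", "FluctuationSummary", "sliding_rms", "nrms",
           "nrms_series", "estimate_pdf", "quartile_summary",
           "psd_band_fraction", "summarize"]


@dataclass
class RmsSeries:
    """Sliding-window RMS of a trace: per-window RMS of mean-subtracted
    samples, reported in mV (for a trace in volts)."""

    times: np.ndarray      # window centres, s
    rms: np.ndarray        # mV
    window: float          # s
    hop: float             # s

    def __post_init__(self) -> None:
        if len(self.times) != len(self.rms):
            raise ValueError("times and rms must have equal length")

    def select(self, t_start: float, t_end: float) -> "RmsSeries":
        """Sub-series of windows centred inside ``[t_start, t_end)``."""
        m = (self.times >= t_start) & (self.times < t_end)
        return RmsSeries(self.times[m], self.rms[m], self.window, self.hop)


@dataclass
class FluctuationSummary:
    nrms: float
    median_rms: float                    # mV
    quartiles: tuple[float, float, float]
    pdf: tuple[np.ndarray, np.ndarray]   # (grid, density)
    band_fraction_3_150: float

    def __post_init__(self) -> None:
        q1, q2, q3 = self.quartiles
        if not (q1 <= q2 <= q3):
            raise ValueError("quartiles must be ordered")


def sliding_rms(trace: Trace, window: float = 0.1, hop: float = 0.05) -> RmsSeries:
    """Per-window RMS of the (per-window) mean-subtracted trace, in mV.

    Vectorized through cumulative sums; windows advance by ``hop`` seconds.
    """
    w = int(round(window * trace.fs))
    h = max(1, int(round(hop * trace.fs)))
    if w < 10:
        raise ValueError("window must span at least 10 samples")
    if h > w:
        raise ValueError("hop must not exceed the window")
    x = trace.values
    if w > len(x):
        raise ValueError("window longer than the trace")
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, len(x) - w + 1, h)
    mean = (s1[starts + w] - s1[starts]) / w
    var = (s2[starts + w] - s2[starts]) / w - mean * mean
    rms = np.sqrt(np.maximum(var, 0.0)) * 1e3
    times = trace.t0_offset + (starts + (w - 1) / 2.0) / trace.fs
    return RmsSeries(times=times, rms=rms, window=w / trace.fs, hop=h / trace.fs)


def nrms(segment: np.ndarray | Trace) -> float:
    """Normalized RMS: standard deviation over median level (dimensionless).

    Scale-invariant, so values are comparable across nanoapertures with
    different absolute transmission.
    """
    x = segment.values if isinstance(segment, Trace) else np.asarray(segment, float)
    med = float(np.median(x))
    if med <= 0:
        raise ValueError("NRMS requires a strictly positive median level")
    return float(np.std(x)) / med


def nrms_series(trace: Trace, sub_duration: float = 1.0) -> np.ndarray:
    """NRMS of consecutive ``sub_duration``-second sub-traces.

    Fluctuation distributions (violin/box summaries) are built from these
    per-second values rather than one whole-trace number.
    """
    n_sub = int(round(sub_duration * trace.fs))
    if n_sub < 1 or n_sub > len(trace.values):
        raise ValueError("sub-segment does not fit in the trace")
    n_full = len(trace.values) // n_sub
    chunks = trace.values[: n_full * n_sub].reshape(n_full, n_sub)
    med = np.median(chunks, axis=1)
    if np.any(med <= 0):
        raise ValueError("NRMS requires strictly positive median levels")
    return chunks.std(axis=1) / med


def estimate_pdf(values: np.ndarray, grid_points: int = 4096,
                 bandwidth: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-KDE probability density of the sample values.

    Same code path as mode normalization, so the PDF argmax equals the
    normalization divisor.  Density integrates to 1 within 1e-6.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1000:
        raise ValueError("PDF estimation needs at least 1000 values")
    return kde_on_grid(values, grid_points, bandwidth)


def quartile_summary(values: np.ndarray) -> tuple[float, float, float]:
    """Linear-interpolation quartiles (q1, q2, q3)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def psd_band_fraction(segment: np.ndarray | Trace, f_lo: float, f_hi: float,
                      fs: float | None = None) -> float:
    """Fraction of spectral power in ``[f_lo, f_hi]``.

    Welch PSD with Hann windows of ~``4/f_lo`` seconds (rounded to a power of
    two) and 50% overlap; the denominator is the power above ``f_lo/2`` so a
    DC offset or slow drift does not dilute the fraction.
    """
    if isinstance(segment, Trace):
        x, fs = segment.values, segment.fs
    else:
        x = np.asarray(segment, dtype=np.float64)
        if fs is None:
            raise ValueError("fs required for a bare array")
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("need 0 < f_lo < f_hi < fs/2")
    if len(x) < 10 * fs / f_lo:
        raise ValueError("segment must span at least 10/f_lo seconds")
    nperseg = 2 ** int(round(math.log2(4.0 * fs / f_lo)))
    nperseg = min(nperseg, len(x))
    freqs, psd = _signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=nperseg // 2, detrend="constant")
    total = psd[freqs >= f_lo / 2].sum()
    in_band = psd[(freqs >= f_lo) & (freqs <= f_hi)].sum()
    return float(in_band / total)


def summarize(trace_segment: Trace, window: float = 0.1, hop: float = 0.05,
              band: tuple[float, float] = (3.0, 150.0)) -> FluctuationSummary:
    """Full fluctuation summary of a (filtered) trapped segment."""
    rms = sliding_rms(trace_segment, window, hop)
    per_second = nrms_series(trace_segment)
    grid, density = estimate_pdf(trace_segment.values)
    return FluctuationSummary(
        nrms=float(np.median(per_second)),
        median_rms=float(np.median(rms.rms)),
        quartiles=quartile_summary(trace_segment.values),
        pdf=(grid, density),
        band_fraction_3_150=psd_band_fraction(trace_segment, *band),
    )
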