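"""Trapping-event detection: mean-shift change points, baseline ``T0``,
step height ``DeltaT``, and the dielectric-loading ratio ``DeltaT/T0``.

Change points are found by binary segmentation on the least-squares
(cumulative-sum) statistic with a BIC-like penalty; levels are estimated by
medians, which are robust to the asymmetric conformational fluctuations of
a trapped protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import decimate, gaussian_lowpass
from .trace import Trace

__all__ = ["TrapEvent", "detect_steps", "characterize_trap", "detect_trap_event"]


@dataclass
class TrapEvent:
    """One trapping event: step timing and dielectric-loading contrast."""

    t_trap: float                 # s
    t_release: float | None       # s, None if the protein stays trapped
    baseline: float               # T0, V (pre-trap level)
    delta_t: float                # DeltaT, V
    ratio: float                  # DeltaT / T0
    confidence: str = "detected"  # {"detected", "none"}

    def __post_init__(self) -> None:
        if self.t_release is not None and not self.t_trap < self.t_release:
            raise ValueError("t_trap must precede t_release")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


def _sse(s1: np.ndarray, s2: np.ndarray, lo: int, hi: int) -> float:
    """Sum of squared residuals of x[lo:hi] about its mean, from cumsums."""
    n = hi - lo
    tot = s1[hi] - s1[lo]
    return (s2[hi] - s2[lo]) - tot * tot / n


def detect_steps(trace: Trace, min_separation: float = 0.5,
                 penalty: float | None = None) -> np.ndarray:
    """Mean-shift change points by penalized binary segmentation.

    ``min_separation`` is in seconds; detected points (sample indices,
    sorted) are at least that far apart and from the trace edges.  The
    default penalty is the BIC-like ``2 sigma^2 log n`` with the noise scale
    estimated from the median absolute deviation of first differences
    (robust to the steps themselves).
    """
    x = trace.values
    sep = max(1, int(round(min_separation * trace.fs)))
    n = len(x)
    if n < 2 * sep:
        raise ValueError("trace shorter than twice the minimum separation")
    if penalty is None:
        mad = np.median(np.abs(np.diff(x) - np.median(np.diff(x))))
        sigma = 1.4826 * mad / math.sqrt(2.0)
        penalty = 2.0 * sigma * sigma * math.log(n)
        if penalty == 0:
            penalty = 1e-300  # noise-free input: any real step is accepted
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    found: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * sep:
            continue
        ks = np.arange(lo + sep, hi - sep + 1)
        if len(ks) == 0:
            continue
        nl = ks - lo
        nr = hi - ks
        tl = s1[ks] - s1[lo]
        tr = s1[hi] - s1[ks]
        sse_split = (s2[ks] - s2[lo] - tl * tl / nl
                     + s2[hi] - s2[ks] - tr * tr / nr)
        best = int(np.argmin(sse_split))
        gain = _sse(s1, s2, lo, hi) - sse_split[best]
        if gain > penalty:
            k = int(ks[best])
            found.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return np.array(sorted(found), dtype=np.int64)


def characterize_trap(trace: Trace, change_points: np.ndarray,
                      settle: float = 0.5) -> TrapEvent:
    """Estimate ``T0``, ``DeltaT`` and the ratio from detected change points.

    The trapping step is the change point with the largest level jump
    (median of the adjacent segments); ``T0`` is the median of the pre-trap
    window, the trapped level the median of the following segment excluding
    a ``settle``-second transient.  A later step whose post level returns to
    within 3 pre-trap noise SDs of ``T0`` is reported as the release.
    """
    cps = np.asarray(change_points, dtype=np.int64)
    if len(cps) == 0:
        raise ValueError("need at least one change point")
    x = trace.values
    edges = np.concatenate(([0], cps, [len(x)]))
    levels = np.array([np.median(x[a:b]) for a, b in zip(edges[:-1], edges[1:])])
    jumps = np.abs(np.diff(levels))
    k = int(np.argmax(jumps))              # index into cps
    i_trap = int(cps[k])
    if i_trap < trace.fs:                  # need >= 1 s of pre-trap baseline
        raise ValueError("no pre-trap window of at least 1 s")
    pre = x[edges[k]:i_trap]
    t0 = float(np.median(pre))
    noise_sd = 1.4826 * float(np.median(np.abs(pre - t0)))

    i_settle = i_trap + int(round(settle * trace.fs))
    i_end = int(edges[k + 2])
    # release: first later change point whose following level returns to T0
    t_release = None
    for j in range(k + 1, len(cps)):
        if abs(levels[j + 1] - t0) <= 3.0 * max(noise_sd, 1e-12):
            t_release = trace.t0_offset + cps[j] / trace.fs
            i_end = int(cps[j])
            break
    if i_settle >= i_end:
        i_settle = i_trap
    trapped = float(np.median(x[i_settle:i_end]))
    delta_t = trapped - t0
    return TrapEvent(t_trap=trace.t0_offset + i_trap / trace.fs,
                     t_release=t_release, baseline=t0, delta_t=delta_t,
                     ratio=delta_t / t0)


def detect_trap_event(trace: Trace, filter_cutoff: float = 1000.0,
                      detect_fs: float = 100.0,
                      min_separation: float = 0.5) -> TrapEvent:
    """Convenience pipeline: filter, decimate to ~``detect_fs``, detect steps,
    characterize the trapping event on the decimated trace."""
    work = trace
    if filter_cutoff and filter_cutoff < trace.fs / 2:
        work = gaussian_lowpass(work, filter_cutoff)
    factor = int(work.fs // detect_fs)
    if factor >= 2:
        work = decimate(work, factor)
    cps = detect_steps(work, min_separation=min_separation)
    return characterize_trap(work, cps)
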