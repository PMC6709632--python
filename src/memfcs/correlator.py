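"""Normalized fluorescence autocorrelation from intensity traces.

The multi-tau scheme evaluates G on a quasi-logarithmic lag grid: the first
two octaves at the raw sampling interval, then ``points_per_octave`` lags
per octave on a trace progressively binned by factors of two. Normalization
is symmetric,

    G(tau) = <I_left I_right> / (<I_left><I_right>) - 1,

with the means taken over the overlapping segments, which removes the
leading-order bias from slow drift and reduces to <dI dI>/<I>^2 for
stationary signals. A brute-force O(N * n_lags) correlator evaluating the
same definition at every integer lag serves as the testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import CorrelationError

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "autocorrelate_direct",
    "autocorrelate_multitau",
    "average_segment_curves",
    "bin_trace",
    "restrict_lags",
]

MIN_FIT_LAGS = 8  # curves shorter than this refuse downstream fitting
_MIN_OVERLAP = 16  # minimum overlapping samples for a lag to be reported


@dataclass
class IntensityTrace:
    """Detected fluorescence versus time at one spot/pixel."""

    values: np.ndarray
    dt: float                      # sampling interval (s)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise CorrelationError("trace must be 1D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise CorrelationError("trace contains non-finite values")
        if np.any(self.values < 0):
            raise CorrelationError("trace contains negative intensities")
        if not (self.dt > 0):
            raise CorrelationError("dt must be > 0")

    def __len__(self):
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def mean_rate(self) -> float:
        """Mean intensity per second (counts/s for photon-counting traces)."""
        return self.mean / self.dt


@dataclass
class CorrelationCurve:
    """Normalized autocorrelation G(tau) on a strictly increasing lag grid."""

    lags: np.ndarray               # s
    G: np.ndarray
    sem: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise CorrelationError("lags and G must have the same shape")
        if len(self.lags) and np.any(np.diff(self.lags) <= 0):
            raise CorrelationError("lags must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)

    def __len__(self):
        return len(self.lags)


def _g_at(values: np.ndarray, k: int) -> float:
    a = values[:-k]
    b = values[k:]
    ma = a.mean()
    mb = b.mean()
    if ma <= 0 or mb <= 0:
        raise CorrelationError(
            "normalization undefined: zero mean intensity in the overlap")
    return float(np.dot(a, b) / (len(a) * ma * mb) - 1.0)


def bin_trace(trace: IntensityTrace, factor: int) -> IntensityTrace:
    """Average consecutive groups of ``factor`` samples (multi-tau binning)."""
    if factor < 1:
        raise CorrelationError("bin factor must be >= 1")
    if factor == 1:
        return trace
    v = trace.values
    n = (len(v) // factor) * factor
    if n < 2 * factor:
        raise CorrelationError("trace too short for this bin factor")
    binned = v[:n].reshape(-1, factor).mean(axis=1)
    return IntensityTrace(binned, trace.dt * factor, dict(trace.meta))


def autocorrelate_direct(trace: IntensityTrace, max_lag: int
                         ) -> CorrelationCurve:
    """Exact correlator: direct summation at every integer lag 1..max_lag."""
    v = trace.values
    if not (1 <= max_lag < len(v)):
        raise CorrelationError("max_lag must satisfy 1 <= max_lag < len(trace)")
    if v.mean() <= 0:
        raise CorrelationError("zero-mean trace: normalization undefined")
    ks = np.arange(1, max_lag + 1)
    G = np.array([_g_at(v, int(k)) for k in ks])
    return CorrelationCurve(lags=ks * trace.dt, G=G,
                            meta={"method": "direct"})


def autocorrelate_multitau(trace: IntensityTrace,
                           points_per_octave: int = 16) -> CorrelationCurve:
    """Multi-tau correlator with progressive factor-2 binning.

    Level 0 evaluates lags 1..2m at the raw interval; level l >= 1 evaluates
    lags m+1..2m on the trace binned by 2^l. Lags whose overlap falls below
    a small floor are dropped rather than reported with huge variance.
    """
    m = int(points_per_octave)
    if m < 1:
        raise CorrelationError("points_per_octave must be >= 1")
    if len(trace) < 2 * m:
        raise CorrelationError(
            f"trace length {len(trace)} below 2 x points_per_octave")
    if trace.values.mean() <= 0:
        raise CorrelationError("zero-mean trace: normalization undefined")

    lags = []
    G = []
    v = trace.values
    level = 0
    while True:
        ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        scale = 1 << level
        emitted = False
        for k in ks:
            if len(v) - k < _MIN_OVERLAP:
                break
            lags.append(k * scale * trace.dt)
            G.append(_g_at(v, k))
            emitted = True
        if not emitted:
            break
        n = (len(v) // 2) * 2
        if n < 2 * (m + 1) + _MIN_OVERLAP:
            break
        v = v[:n].reshape(-1, 2).mean(axis=1)
        level += 1
    return CorrelationCurve(lags=np.asarray(lags), G=np.asarray(G),
                            meta={"method": "multitau",
                                  "points_per_octave": m})


def average_segment_curves(trace: IntensityTrace, n_segments: int = 8,
                           points_per_octave: int = 16) -> CorrelationCurve:
    """Correlate equal contiguous segments and average the curves.

    Standard FCS curve averaging: the per-lag scatter across segments gives
    an empirical standard error usable as fit weights downstream. Note the
    symmetric normalization subtracts each segment's own mean, which biases
    G downward by ~2 tau_D/T_segment of the amplitude; keep segments at
    least a few hundred transit times long.
    """
    if n_segments < 2:
        raise CorrelationError("need at least 2 segments")
    seg_len = len(trace) // n_segments
    if seg_len < 2 * points_per_octave:
        raise CorrelationError("segments too short for the correlator")
    curves = []
    for s in range(n_segments):
        seg = IntensityTrace(trace.values[s * seg_len:(s + 1) * seg_len],
                             trace.dt)
        curves.append(autocorrelate_multitau(seg, points_per_octave))
    Gs = np.vstack([c.G for c in curves])
    sem = Gs.std(axis=0, ddof=1) / np.sqrt(n_segments)
    return CorrelationCurve(lags=curves[0].lags, G=Gs.mean(axis=0), sem=sem,
                            meta={"method": "multitau_segment_mean",
                                  "n_segments": n_segments,
                                  "points_per_octave": points_per_octave})


def restrict_lags(curve: CorrelationCurve, tmin: float = 0.0,
                  tmax: float = np.inf) -> CorrelationCurve:
    """Curve restricted to lags in [tmin, tmax]."""
    keep = (curve.lags >= tmin) & (curve.lags <= tmax)
    return CorrelationCurve(curve.lags[keep], curve.G[keep],
                            None if curve.sem is None else curve.sem[keep],
                            dict(curve.meta))
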