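"""Liquid-ordered partitioning (%Lo) from two-phase vesicle line profiles.

A line across the equator of a phase-separated vesicle crosses the
membrane twice, once per phase (opposite sides are used to cancel
excitation-polarization artifacts). With background-subtracted membrane
intensities I_Lo and I_Ld at the two crossings,

    %Lo = 100 * I_Lo / (I_Lo + I_Ld),

and a probe prefers the liquid-ordered phase when %Lo > 50%. Phase
assignment of the crossings comes from a reference channel carrying a
disordered-phase marker (high reference signal = Ld).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks
from skimage.measure import profile_line

from .errors import ConfigError, ProfileError

__all__ = ["LineProfile", "PartitionResult", "extract_crossings",
           "percent_lo"]


@dataclass
class LineProfile:
    """Intensity profile along a user line, with its two membrane crossings."""

    intensities: np.ndarray
    positions: np.ndarray
    peak_indices: Tuple[int, int]
    crossing_intensities: Tuple[float, float]   # background-subtracted
    background: float
    ref_intensities: Optional[np.ndarray] = None
    phase_labels: Optional[Tuple[str, str]] = None  # per crossing
    meta: dict = field(default_factory=dict)

    @property
    def i_lo(self) -> float:
        if self.phase_labels is None:
            raise ProfileError("phases were not assigned (no reference channel)")
        return self.crossing_intensities[self.phase_labels.index("lo")]

    @property
    def i_ld(self) -> float:
        if self.phase_labels is None:
            raise ProfileError("phases were not assigned (no reference channel)")
        return self.crossing_intensities[self.phase_labels.index("ld")]


@dataclass
class PartitionResult:
    percent_lo: float
    preference: str                 # "ordered" | "disordered"
    i_lo: float
    i_ld: float

    def to_dict(self) -> dict:
        return {"percent_lo": self.percent_lo, "preference": self.preference,
                "i_lo": self.i_lo, "i_ld": self.i_ld}


def _peak_value(profile: np.ndarray, idx: int, background: float,
                window: int, integrated: bool) -> float:
    lo = max(0, idx - window)
    hi = min(len(profile), idx + window + 1)
    if integrated:
        return float(np.sum(profile[lo:hi] - background))
    return float(np.mean(profile[lo:hi]) - background)


def extract_crossings(image: np.ndarray, line_endpoints,
                      reference: Optional[np.ndarray] = None,
                      subtract_background: bool = True,
                      integrated: bool = False,
                      peak_window: int = 1) -> LineProfile:
    """Locate the two membrane crossings along a line through a vesicle.

    Parameters
    ----------
    image:
        2D signal-channel image.
    line_endpoints:
        ((row0, col0), (row1, col1)) endpoints of the profile line; it must
        cross the vesicle rim exactly twice.
    reference:
        2D disordered-phase marker channel; the crossing with the higher
        reference signal is labelled Ld. Without it the crossings are
        returned unlabelled and %Lo cannot be formed.
    subtract_background:
        Subtract the median of the off-membrane profile (default); set
        False to use raw peak values.
    integrated:
        Sum over the crossing window instead of the (default) peak value,
        taken as the mean over +-``peak_window`` pixels around the maximum.
    """
    (r0, c0), (r1, c1) = line_endpoints
    prof = profile_line(np.asarray(image, dtype=float), (r0, c0), (r1, c1),
                        order=1, mode="constant")
    if len(prof) < 8:
        raise ProfileError("line too short")
    n = len(prof)

    # provisional peaks: one per half (opposite sides of the vesicle)
    left_idx = int(np.argmax(prof[: n // 2]))
    right_idx = n // 2 + int(np.argmax(prof[n // 2:]))
    w_excl = max(3, n // 10)
    mask = np.ones(n, dtype=bool)
    for p in (left_idx, right_idx):
        mask[max(0, p - w_excl): p + w_excl + 1] = False
    off = prof[mask]
    background = float(np.median(off)) if subtract_background and len(off) \
        else 0.0

    span = float(prof.max() - background)
    if span <= 0:
        raise ProfileError("line does not cross the vesicle rim")
    peaks, _ = find_peaks(
        np.concatenate(([background], prof, [background])),
        height=background + 0.33 * span, distance=max(2, n // 4))
    peaks = peaks - 1
    if len(peaks) != 2:
        raise ProfileError(
            f"expected exactly 2 membrane crossings, found {len(peaks)}")
    for p in peaks:
        if prof[p] - background < 0.2 * span + 3.0 * np.std(off, ddof=0):
            raise ProfileError("a crossing is not above the local background")

    vals = tuple(_peak_value(prof, int(p), background, peak_window,
                             integrated) for p in peaks)

    ref_prof = None
    labels = None
    if reference is not None:
        ref_prof = profile_line(np.asarray(reference, dtype=float),
                                (r0, c0), (r1, c1), order=1, mode="constant")
        ref_vals = [float(np.mean(ref_prof[max(0, p - peak_window):
                                           p + peak_window + 1]))
                    for p in peaks]
        ref_span = max(max(ref_vals), 1e-12)
        if abs(ref_vals[0] - ref_vals[1]) < 0.1 * ref_span:
            raise ProfileError("ambiguous phase assignment: reference signal "
                               "similar at both crossings")
        if ref_vals[0] > ref_vals[1]:
            labels = ("ld", "lo")
        else:
            labels = ("lo", "ld")

    return LineProfile(intensities=prof, positions=np.arange(n, dtype=float),
                       peak_indices=(int(peaks[0]), int(peaks[1])),
                       crossing_intensities=vals, background=background,
                       ref_intensities=ref_prof, phase_labels=labels)


def percent_lo(i_lo: float, i_ld: float) -> PartitionResult:
    """%Lo = 100 * I_Lo / (I_Lo + I_Ld), with the >50% preference rule."""
    if i_lo < 0 or i_ld < 0:
        raise ConfigError("crossing intensities must be >= 0")
    total = i_lo + i_ld
    if total <= 0:
        raise ConfigError("both crossing intensities are zero")
    pct = 100.0 * i_lo / total
    return PartitionResult(percent_lo=pct,
                           preference="ordered" if pct > 50.0
                           else "disordered",
                           i_lo=float(i_lo), i_ld=float(i_ld))
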