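"""Analytic FCS models, nonlinear fitting, and derived physical quantities.

The model is the standard two-dimensional FCS law with optional anomalous
exponent and triplet blinking,

    G(tau) = G0 * [1 + T/(1-T) * exp(-tau/tau_T)]
                * sum_i f_i / (1 + (tau/tau_D,i)^alpha),

where G0 = 1/N is the inverse mean occupancy of the observation spot,
tau_D,i the transit times, f_i the component fractions (sum 1), alpha the
anomalous exponent (1 for free diffusion), and T/tau_T the triplet fraction
and relaxation time. Transit times convert to diffusion coefficients via
the spot calibration, D = w0^2 / (4 tau_D), with w0 the 1/e^2 radius.
Molecular brightness (counts per molecule) is cpm = <I> * G0 = <I> / N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .correlator import (MIN_FIT_LAGS, CorrelationCurve, IntensityTrace,
                         autocorrelate_multitau, restrict_lags)
from .errors import ConfigError, FitError

__all__ = [
    "SpotCalibration",
    "FCSModelSpec",
    "FCSFitResult",
    "model_g",
    "fit_curve",
    "bootstrap_fit_trace",
    "transit_to_D",
    "counts_per_molecule",
]

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SpotCalibration:
    """Gaussian observation-spot geometry.

    ``effective_area`` (pi w0^2 / 2) is the lateral observation area as
    usually quoted for confocal spots; a 250 nm FWHM gives ~0.07 um^2.
    ``amplitude_area`` (pi w0^2) is the area that links amplitude and
    concentration, G(0) = 1 / (c * pi w0^2), for this detection profile.
    """

    fwhm_nm: float

    @property
    def w0_um(self) -> float:
        return self.fwhm_nm * 1e-3 / _SQRT_2LN2

    @property
    def effective_area_um2(self) -> float:
        return math.pi * self.w0_um ** 2 / 2.0

    @property
    def amplitude_area_um2(self) -> float:
        return math.pi * self.w0_um ** 2

    @classmethod
    def from_fwhm(cls, fwhm_nm: float) -> "SpotCalibration":
        return cls(fwhm_nm=fwhm_nm)

    @classmethod
    def from_waist(cls, w0_nm: float) -> "SpotCalibration":
        return cls(fwhm_nm=w0_nm * _SQRT_2LN2)


@dataclass
class FCSModelSpec:
    """Which terms of the 2D FCS law are free in a fit."""

    n_components: int = 1
    anomalous: bool = False
    triplet: bool = False
    offset: bool = False   # free additive baseline G_inf absorbing the
    # finite-trace normalization bias (~ -2 int G / T); recommended when the
    # trace is shorter than a few hundred transit times
    # bounds; triplet time window is a generic guess, not a measured value
    tau_t_bounds: tuple = (1e-6, 1e-4)
    alpha_bounds: tuple = (0.3, 2.0)

    def __post_init__(self):
        if self.n_components not in (1, 2):
            raise ConfigError("n_components must be 1 or 2")


@dataclass
class FCSFitResult:
    """Fitted FCS parameters and diagnostics."""

    g0: float
    tau_d: tuple                     # s, per component
    fractions: tuple
    alpha: float = 1.0
    tau_t: float = 0.0
    t_frac: float = 0.0
    g_inf: float = 0.0
    d: Optional[tuple] = None        # um^2/s, per component
    cpm: Optional[float] = None      # brightness, <I> * G0
    redchi: float = float("nan")
    success: bool = True
    message: str = ""
    stderr: dict = field(default_factory=dict)
    bootstrap_sd: dict = field(default_factory=dict)

    @property
    def n(self) -> float:
        """Mean occupancy of the spot, N = 1/G0."""
        return 1.0 / self.g0

    @property
    def tau_d_ms(self) -> tuple:
        return tuple(1e3 * t for t in self.tau_d)

    def to_dict(self) -> dict:
        return {
            "g0": self.g0, "n": self.n, "tau_d_s": list(self.tau_d),
            "fractions": list(self.fractions), "alpha": self.alpha,
            "tau_t_s": self.tau_t, "triplet_fraction": self.t_frac,
            "g_inf": self.g_inf,
            "d_um2_per_s": None if self.d is None else list(self.d),
            "cpm": self.cpm, "redchi": self.redchi,
            "success": self.success, "message": self.message,
            "stderr": self.stderr, "bootstrap_sd": self.bootstrap_sd,
        }


def model_g(tau, spec: FCSModelSpec, params: dict):
    """Evaluate the 2D FCS law at lags ``tau`` (s).

    ``params`` uses keys g0, tau_d1[, f1, tau_d2], alpha, tau_t, t_frac
    (missing optional keys default to the non-anomalous, triplet-free law).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ConfigError("lags must be positive")
    g0 = params["g0"]
    alpha = params.get("alpha", 1.0) if spec.anomalous else 1.0
    if spec.n_components == 1:
        comps = 1.0 / (1.0 + (tau / params["tau_d1"]) ** alpha)
    else:
        f1 = params["f1"]
        comps = (f1 / (1.0 + (tau / params["tau_d1"]) ** alpha)
                 + (1.0 - f1) / (1.0 + (tau / params["tau_d2"]) ** alpha))
    if spec.triplet:
        T = params.get("t_frac", 0.0)
        tau_t = params.get("tau_t", 1e-6)
        trip = 1.0 + T / (1.0 - T) * np.exp(-tau / tau_t)
    else:
        trip = 1.0
    return g0 * trip * comps + params.get("g_inf", 0.0)


def _make_params(spec: FCSModelSpec, curve: CorrelationCurve,
                 tau_init: float, g0_init: float) -> lmfit.Parameters:
    p = lmfit.Parameters()
    lag_lo, lag_hi = curve.lags[0], curve.lags[-1]
    p.add("g0", value=max(g0_init, 1e-8), min=1e-10, max=1e6)
    p.add("tau_d1", value=tau_init, min=lag_lo / 10, max=lag_hi * 100)
    if spec.n_components == 2:
        p.add("f1", value=0.5, min=0.0, max=1.0)
        p.add("tau_d2", value=tau_init / 4, min=lag_lo / 10, max=lag_hi * 100)
    if spec.anomalous:
        p.add("alpha", value=1.0, min=spec.alpha_bounds[0],
              max=spec.alpha_bounds[1])
    if spec.triplet:
        p.add("t_frac", value=0.05, min=0.0, max=0.8)
        p.add("tau_t", value=math.sqrt(spec.tau_t_bounds[0]
                                       * spec.tau_t_bounds[1]),
              min=spec.tau_t_bounds[0], max=spec.tau_t_bounds[1])
    if spec.offset:
        lim = 0.5 * max(g0_init, 1e-8)
        p.add("g_inf", value=0.0, min=-lim, max=lim)
    return p


def _initial_guesses(curve: CorrelationCurve):
    """Amplitude from the earliest lags; tau_D from the half-decay lag."""
    n_head = max(2, len(curve) // 20)
    g0 = float(np.mean(curve.G[:n_head]))
    if not np.isfinite(g0) or g0 <= 0:
        g0 = max(float(np.max(curve.G)), 1e-6)
    half = g0 / 2.0
    below = np.nonzero(curve.G <= half)[0]
    tau_half = float(curve.lags[below[0]]) if len(below) else \
        float(np.sqrt(curve.lags[0] * curve.lags[-1]))
    return g0, tau_half


def fit_curve(curve: CorrelationCurve, spec: FCSModelSpec,
              calibration: Optional[SpotCalibration] = None,
              mean_intensity: Optional[float] = None,
              n_starts: int = 3, seed: int = 0) -> FCSFitResult:
    """Weighted least-squares fit of the FCS model to a correlation curve.

    Weights are 1/sem where a finite positive per-lag standard error is
    available, else unity. Multi-start initialization (amplitude/half-decay
    based plus perturbed restarts) guards against local minima; a fit that
    still fails is returned flagged invalid rather than silently defaulted.
    """
    if len(curve) < MIN_FIT_LAGS:
        raise FitError(f"curve has {len(curve)} lags; need >= {MIN_FIT_LAGS}")
    if not np.all(np.isfinite(curve.G)):
        raise FitError("curve contains non-finite values")

    if curve.sem is not None:
        sem = np.where(np.isfinite(curve.sem) & (curve.sem > 0),
                       curve.sem, np.nan)
        fallback = np.nanmedian(sem)
        if not np.isfinite(fallback) or fallback <= 0:
            weights = np.ones_like(curve.G)
        else:
            weights = 1.0 / np.where(np.isfinite(sem), sem, fallback)
    else:
        weights = np.ones_like(curve.G)

    def residual(p):
        vals = {k: p[k].value for k in p}
        return (model_g(curve.lags, spec, vals) - curve.G) * weights

    g0_init, tau_init = _initial_guesses(curve)
    rng = np.random.default_rng(seed)
    starts = [(g0_init, tau_init),
              (g0_init, float(np.sqrt(curve.lags[0] * curve.lags[-1])))]
    while len(starts) < max(2, n_starts):
        starts.append((g0_init * rng.uniform(0.5, 2.0),
                       tau_init * rng.uniform(0.3, 3.0)))

    best = None
    for g0_s, tau_s in starts[:max(2, n_starts)]:
        params = _make_params(spec, curve, tau_s, g0_s)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if not np.all(np.isfinite([p.value for p in res.params.values()])):
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return FCSFitResult(g0=float("nan"), tau_d=(float("nan"),),
                            fractions=(1.0,), success=False,
                            message="fit did not converge from any start")

    p = {k: best.params[k].value for k in best.params}
    stderr = {k: best.params[k].stderr for k in best.params
              if best.params[k].stderr is not None}
    if spec.n_components == 1:
        tau_d = (p["tau_d1"],)
        fracs = (1.0,)
    else:
        tau_d = (p["tau_d1"], p["tau_d2"])
        fracs = (p["f1"], 1.0 - p["f1"])
    result = FCSFitResult(
        g0=p["g0"], tau_d=tau_d, fractions=fracs,
        alpha=p.get("alpha", 1.0), tau_t=p.get("tau_t", 0.0),
        t_frac=p.get("t_frac", 0.0), g_inf=p.get("g_inf", 0.0),
        redchi=best.redchi, success=True, stderr=stderr)
    if calibration is not None:
        result.d = tuple(transit_to_D(t, calibration) for t in tau_d)
    if mean_intensity is not None:
        result.cpm = counts_per_molecule(mean_intensity, result)
    return result


def bootstrap_fit_trace(trace: IntensityTrace, spec: FCSModelSpec,
                        calibration: Optional[SpotCalibration] = None,
                        n_bootstrap: int = 10,
                        rng: Optional[np.random.Generator] = None,
                        points_per_octave: int = 16,
                        tmin: float = 0.0, tmax: float = np.inf) -> dict:
    """Curve-level bootstrap: refit curves from random contiguous segments.

    Draws ``n_bootstrap`` half-length sub-segments of the trace, correlates
    and fits each, and returns the parameter spread as standard deviations.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(trace)
    half = n // 2
    samples: dict = {}
    for _ in range(n_bootstrap):
        start = int(rng.integers(0, n - half + 1))
        seg = IntensityTrace(trace.values[start:start + half], trace.dt)
        curve = restrict_lags(
            autocorrelate_multitau(seg, points_per_octave), tmin, tmax)
        try:
            fit = fit_curve(curve, spec, calibration)
        except FitError:
            continue
        if not fit.success:
            continue
        rec = {"g0": fit.g0, "tau_d1": fit.tau_d[0], "alpha": fit.alpha}
        if fit.d is not None:
            rec["d1"] = fit.d[0]
        for k, v in rec.items():
            samples.setdefault(k, []).append(v)
    return {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for k, v in samples.items()}


def transit_to_D(tau_d: float, calibration: SpotCalibration) -> float:
    """Diffusion coefficient from a transit time: D = w0^2 / (4 tau_D)."""
    if calibration is None:
        raise ConfigError("a spot calibration is required to convert "
                          "transit times to diffusion coefficients")
    if not (tau_d > 0):
        raise ConfigError("tau_d must be > 0")
    return calibration.w0_um ** 2 / (4.0 * tau_d)


def counts_per_molecule(mean_intensity: float, fit: FCSFitResult) -> float:
    """Molecular brightness cpm = <I> * G0 (= <I>/N)."""
    if mean_intensity < 0:
        raise ConfigError("mean intensity must be >= 0")
    if not fit.success:
        raise FitError("cannot compute cpm from an invalid fit")
    if not (fit.g0 > 0):
        raise FitError("cpm undefined for non-positive amplitude")
    return mean_intensity * fit.g0
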