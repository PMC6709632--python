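"""Transit-time population statistics: log-normal models and BIC selection.

Pooled scanning-FCS transit times are modelled as a log-normal (free
diffusion) or a two-component log-normal mixture (hindered diffusion). In
the mixture, the slow component C1 carries weight 1 - B and the fast
component C2 weight B; e^mu is the median transit time of a component.
Model choice between single and double is by the Bayesian Information
Criterion, BIC = k ln n - 2 ln L, with k = 2 and 5 free parameters
respectively; the lower BIC wins and the margin is reported.

Primary estimates are maximum-likelihood on the raw samples (closed form
for the single model, expectation-maximization for the mixture). The three
histogramming modes (linear, logarithmic, cumulative) with least-squares
log-normal fits are provided as diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .errors import ConfigError, FitError

__all__ = [
    "TransitTimeSet",
    "LogNormalModelFit",
    "ModelSelection",
    "Histogram",
    "fit_lognormal",
    "fit_double_lognormal",
    "select_model_bic",
    "histogram_modes",
]

SIGMA_FLOOR = 1e-3  # log-scale floor preventing degenerate spikes


@dataclass
class TransitTimeSet:
    """Pooled transit times in milliseconds."""

    times_ms: np.ndarray
    labels: Optional[np.ndarray] = None
    min_n_selection: int = 50

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.ndim != 1:
            raise ConfigError("times must be a 1D array")
        if len(self.times_ms) < 1:
            raise ConfigError("empty transit-time set")
        if not np.all(np.isfinite(self.times_ms)) or np.any(self.times_ms <= 0):
            raise ConfigError("all transit times must be finite and > 0")

    def __len__(self):
        return len(self.times_ms)

    @property
    def log_times(self) -> np.ndarray:
        return np.log(self.times_ms)


@dataclass
class LogNormalModelFit:
    """MLE result for the single or double log-normal model.

    ``mu``/``sigma``/``weights`` are per component on the log-ms scale,
    ordered slow first (descending e^mu) for the double model. ``b`` is the
    fast-component weight, so the slow fraction is 1 - B.
    """

    model: str                        # "single" | "double"
    mu: tuple
    sigma: tuple
    weights: tuple
    log_likelihood: float
    bic: float
    n: int
    degenerate: bool = False
    converged: bool = True

    @property
    def e_mu_ms(self) -> tuple:
        """Median transit time(s), e^mu, in ms."""
        return tuple(math.exp(m) for m in self.mu)

    @property
    def b(self) -> float:
        """Weight of the fast component (the slow fraction is 1 - B)."""
        return self.weights[-1] if self.model == "double" else 1.0

    @property
    def k(self) -> int:
        return 2 if self.model == "single" else 5

    def to_dict(self) -> dict:
        return {"model": self.model, "mu": list(self.mu),
                "sigma": list(self.sigma), "weights": list(self.weights),
                "e_mu_ms": list(self.e_mu_ms), "b": self.b,
                "log_likelihood": self.log_likelihood, "bic": self.bic,
                "n": self.n, "degenerate": self.degenerate,
                "converged": self.converged}


def _lognormal_loglik(y: np.ndarray, mu: float, sigma: float) -> float:
    # y = ln t; the Jacobian term -sum(y) converts the normal density in y
    # to the log-normal density in t
    return float(np.sum(norm.logpdf(y, mu, sigma)) - np.sum(y))


def fit_lognormal(times: TransitTimeSet) -> LogNormalModelFit:
    """Closed-form MLE of the single log-normal model."""
    y = times.log_times
    n = len(y)
    if n < 2:
        raise ConfigError("need at least 2 samples")
    mu = float(np.mean(y))
    sigma = float(np.sqrt(np.mean((y - mu) ** 2)))
    degenerate = sigma < SIGMA_FLOOR
    sigma_eff = max(sigma, SIGMA_FLOOR)
    ll = _lognormal_loglik(y, mu, sigma_eff)
    bic = 2 * math.log(n) - 2.0 * ll
    return LogNormalModelFit(model="single", mu=(mu,), sigma=(sigma_eff,),
                             weights=(1.0,), log_likelihood=ll, bic=bic,
                             n=n, degenerate=degenerate)


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _normal_logpdf(y, mu, sigma):
    return -0.5 * ((y - mu) / sigma) ** 2 - math.log(sigma) - _LOG_SQRT_2PI


def _em(y, mu1, s1, mu2, s2, w1, tol=1e-9, max_iter=500):
    """EM for a two-component normal mixture on y = ln t."""
    n = len(y)
    prev = -np.inf
    ll = prev
    for it in range(max_iter):
        la = math.log(max(w1, 1e-300)) + _normal_logpdf(y, mu1, s1)
        lb = math.log(max(1 - w1, 1e-300)) + _normal_logpdf(y, mu2, s2)
        tot = np.logaddexp(la, lb)
        ll = float(np.sum(tot))
        r = np.exp(la - tot)
        if abs(ll - prev) < tol * (abs(ll) + 1.0):
            prev = ll
            break
        prev = ll
        n1 = r.sum()
        n2 = n - n1
        if n1 < 1e-10 or n2 < 1e-10:
            break
        mu1 = float(np.dot(r, y) / n1)
        mu2 = float(np.dot(1 - r, y) / n2)
        s1 = max(math.sqrt(max(np.dot(r, (y - mu1) ** 2) / n1, 0.0)),
                 SIGMA_FLOOR)
        s2 = max(math.sqrt(max(np.dot(1 - r, (y - mu2) ** 2) / n2, 0.0)),
                 SIGMA_FLOOR)
        w1 = float(n1 / n)
    return mu1, s1, mu2, s2, w1, ll


def fit_double_lognormal(times: TransitTimeSet,
                         seed: int = 0) -> LogNormalModelFit:
    """MLE of the two-component log-normal mixture by multi-start EM.

    Starts: a median split of ln t, two perturbed restarts, and a
    near-degenerate start at the single-model fit (which guarantees the
    mixture log-likelihood is at least the single-model one).
    """
    y = times.log_times
    n = len(y)
    if n < times.min_n_selection:
        raise ConfigError(
            f"need >= {times.min_n_selection} samples for the mixture model")
    rng = np.random.default_rng(seed)
    med = float(np.median(y))
    lo, hi = y[y <= med], y[y > med]
    s_all = max(float(np.std(y)), SIGMA_FLOOR)
    single = fit_lognormal(times)

    starts = [
        (float(np.mean(lo)), max(float(np.std(lo)), SIGMA_FLOOR),
         float(np.mean(hi)), max(float(np.std(hi)), SIGMA_FLOOR), 0.5),
        (single.mu[0], single.sigma[0], single.mu[0], single.sigma[0], 0.999),
    ]
    for _ in range(2):
        starts.append((med - s_all * rng.uniform(0.3, 1.5), s_all,
                       med + s_all * rng.uniform(0.3, 1.5), s_all,
                       rng.uniform(0.25, 0.75)))

    best = None
    for st in starts:
        fit = _em(y, *st)
        if not np.isfinite(fit[-1]):
            continue
        if best is None or fit[-1] > best[-1]:
            best = fit
    if best is None:
        raise FitError("mixture EM did not converge from any start")
    mu1, s1, mu2, s2, w1, ll = best
    ll = ll - float(np.sum(y))  # Jacobian: normal density in ln t -> density in t
    comps = sorted([(mu1, s1, w1), (mu2, s2, w2 := 1 - w1)],
                   key=lambda c: -c[0])  # slow (large e^mu) first
    bic = 5 * math.log(n) - 2.0 * ll
    degenerate = any(c[1] <= SIGMA_FLOOR for c in comps)
    return LogNormalModelFit(
        model="double",
        mu=(comps[0][0], comps[1][0]),
        sigma=(comps[0][1], comps[1][1]),
        weights=(comps[0][2], comps[1][2]),
        log_likelihood=ll, bic=bic, n=n, degenerate=degenerate)


@dataclass
class ModelSelection:
    winner: LogNormalModelFit
    single: LogNormalModelFit
    double: LogNormalModelFit

    @property
    def delta_bic(self) -> float:
        """BIC(double) - BIC(single); negative favors the double model."""
        return self.double.bic - self.single.bic

    def to_dict(self) -> dict:
        return {"winner": self.winner.model, "delta_bic": self.delta_bic,
                "single": self.single.to_dict(),
                "double": self.double.to_dict()}


def select_model_bic(times: TransitTimeSet, seed: int = 0) -> ModelSelection:
    """Fit both models and select the lower BIC (no extra threshold)."""
    single = fit_lognormal(times)
    double = fit_double_lognormal(times, seed=seed)
    if not (single.converged and double.converged):
        raise FitError("model selection aborted: a candidate fit is invalid")
    winner = single if single.bic <= double.bic else double
    return ModelSelection(winner=winner, single=single, double=double)


@dataclass
class Histogram:
    """Binned view of the transit times plus a least-squares model fit."""

    mode: str                      # linear | logarithmic | cumulative
    edges: np.ndarray              # bin edges (ms); sample grid for cumulative
    heights: np.ndarray            # density / ECDF values
    fit_mu: float = float("nan")
    fit_sigma: float = float("nan")
    low_mass: bool = False

    @property
    def e_mu_ms(self) -> float:
        return math.exp(self.fit_mu)


def _fit_pdf_linear(centers, heights):
    def pdf(t, mu, sigma):
        return np.exp(-(np.log(t) - mu) ** 2 / (2 * sigma ** 2)) \
            / (t * sigma * math.sqrt(2 * math.pi))
    p, _ = curve_fit(pdf, centers, heights,
                     p0=(float(np.log(np.average(centers, weights=heights
                                                 + 1e-300))), 0.5),
                     maxfev=10000)
    return p


def histogram_modes(times: TransitTimeSet, mode: str,
                    n_bins: int = 30) -> Histogram:
    """Linear, logarithmic, or cumulative histogram with a log-normal fit.

    These reproduce the three diagnostic views of the pooled transit times;
    the MLE fits remain the primary estimates.
    """
    t = times.times_ms
    if mode == "linear":
        heights, edges = np.histogram(t, bins=n_bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        low_mass = int(np.sum(heights > 0)) < 5
        try:
            mu, sigma = _fit_pdf_linear(centers[heights > 0],
                                        heights[heights > 0])
        except Exception:
            mu = sigma = float("nan")
        return Histogram(mode, edges, heights, float(mu), float(abs(sigma)),
                         low_mass)
    if mode == "logarithmic":
        y = times.log_times
        heights, edges = np.histogram(y, bins=n_bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        low_mass = int(np.sum(heights > 0)) < 5

        def npdf(x, mu, sigma):
            return norm.pdf(x, mu, sigma)
        try:
            p, _ = curve_fit(npdf, centers, heights,
                             p0=(float(np.mean(y)), float(np.std(y)) + 1e-6),
                             maxfev=10000)
            mu, sigma = p
        except Exception:
            mu = sigma = float("nan")
        return Histogram(mode, np.exp(edges), heights, float(mu),
                         float(abs(sigma)), low_mass)
    if mode == "cumulative":
        xs = np.sort(t)
        ecdf = (np.arange(1, len(xs) + 1)) / len(xs)

        def cdf(x, mu, sigma):
            return norm.cdf(np.log(x), mu, sigma)
        try:
            p, _ = curve_fit(cdf, xs, ecdf,
                             p0=(float(np.mean(np.log(xs))),
                                 float(np.std(np.log(xs))) + 1e-6),
                             maxfev=10000)
            mu, sigma = p
        except Exception:
            mu = sigma = float("nan")
        return Histogram(mode, xs, ecdf, float(mu), float(abs(sigma)),
                         low_mass=len(xs) < 5)
    raise ConfigError("mode must be linear, logarithmic, or cumulative")
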