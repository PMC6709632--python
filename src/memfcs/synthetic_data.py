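"""Seeded generators for every input the analysis pipeline consumes.

Each generator returns its data plus a :class:`GroundTruthRecord` capturing
the generating parameters, the seed, and the downstream quantities the
pipeline should recover; the record is sufficient to regenerate the data
bit-identically and round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np
from skimage.filters import gaussian as gaussian_blur

from .errors import ConfigError
from .sfcs_pipeline import SFCSCarpet, n_scan_cycles
from .simulator import SimulationConfig, run_simulation
from .transit_stats import TransitTimeSet

__all__ = [
    "GroundTruthRecord",
    "generate_transit_samples",
    "generate_two_phase_vesicle",
    "generate_carpet",
]


@dataclass
class GroundTruthRecord:
    """Provenance sidecar: generator name, parameters, seed, expectations."""

    generator: str
    params: dict
    seed: int
    expected: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "GroundTruthRecord":
        try:
            d = json.loads(s)
        except json.JSONDecodeError:
            with open(s) as fh:
                d = json.load(fh)
        return cls(**d)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def generate_transit_samples(model: str, params: dict, n: int, seed: int
                             ) -> Tuple[TransitTimeSet, GroundTruthRecord]:
    """Draw i.i.d. transit times (ms) from a (mixture of) log-normal(s).

    ``model='single'`` takes ``{'mu', 'sigma'}`` (log-ms scale);
    ``model='double'`` takes ``{'mu1','sigma1','mu2','sigma2','b'}`` where
    ``b`` is the mixing weight of the first-listed component. A degenerate
    mixture (b in {0, 1}) delegates to the single-component path, so it is
    draw-for-draw identical to the corresponding single model at the same
    seed.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if model == "single":
        mu, sigma = params["mu"], params["sigma"]
        if sigma < 0:
            raise ConfigError("sigma must be >= 0")
        times = np.exp(mu + sigma * rng.standard_normal(n))
    elif model == "double":
        b = params["b"]
        if not (0.0 <= b <= 1.0):
            raise ConfigError("mixture weight b must be in [0, 1]")
        if b == 1.0:
            return _delegate_single(params, "1", n, seed, model_params=params)
        if b == 0.0:
            return _delegate_single(params, "2", n, seed, model_params=params)
        comp1 = rng.random(n) < b
        z = rng.standard_normal(n)
        mu = np.where(comp1, params["mu1"], params["mu2"])
        sigma = np.where(comp1, params["sigma1"], params["sigma2"])
        if np.any(sigma < 0):
            raise ConfigError("sigmas must be >= 0")
        times = np.exp(mu + sigma * z)
    else:
        raise ConfigError("model must be 'single' or 'double'")
    record = GroundTruthRecord(
        generator="transit_samples",
        params={"model": model, **params, "n": n}, seed=seed,
        expected=_expected_transit(model, params))
    return TransitTimeSet(times), record


def _delegate_single(params, which, n, seed, model_params):
    sub = {"mu": params[f"mu{which}"], "sigma": params[f"sigma{which}"]}
    times, _ = generate_transit_samples("single", sub, n, seed)
    record = GroundTruthRecord(
        generator="transit_samples",
        params={"model": "double", **model_params, "n": n}, seed=seed,
        expected=_expected_transit("single", sub))
    return times, record


def _expected_transit(model, params):
    if model == "single":
        return {"e_mu_ms": float(np.exp(params["mu"])),
                "sigma": params["sigma"]}
    return {"e_mu_ms": [float(np.exp(params["mu1"])),
                        float(np.exp(params["mu2"]))],
            "sigma": [params["sigma1"], params["sigma2"]],
            "b": params["b"]}


def generate_two_phase_vesicle(radius_px: int = 40, i_lo: float = 60.0,
                               i_ld: float = 40.0, noise_sd: float = 0.0,
                               seed: int = 0, ring_width_px: int = 3,
                               blur_sigma: float = 0.0,
                               margin_px: int = 12):
    """Synthetic equatorial image of a phase-separated vesicle.

    A circular rim (ring) whose right half (x >= center) carries the
    ordered-phase intensity ``i_lo`` and left half the disordered-phase
    ``i_ld``; the phase boundary sits at the top/bottom poles, so a
    horizontal equatorial line crosses each phase at its angular center.
    The image is optionally blurred (point-spread proxy) and carries
    additive Gaussian noise. A second channel marks the Ld half (the
    disordered-phase reference marker).

    Returns ``(image, reference, record)``; use
    ``record.params['line_endpoints']`` as the equatorial line.
    """
    if radius_px < 10:
        raise ConfigError("radius_px must be >= 10")
    rng = np.random.default_rng(seed)
    size = 2 * (radius_px + margin_px) + 1
    c = radius_px + margin_px
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(xx - c, yy - c)
    ring = np.abs(r - radius_px) <= ring_width_px / 2.0
    right = xx >= c
    image = np.zeros((size, size), dtype=float)
    image[ring & right] = i_lo
    image[ring & ~right] = i_ld
    reference = np.zeros_like(image)
    reference[ring & ~right] = 100.0
    if blur_sigma > 0:
        image = gaussian_blur(image, sigma=blur_sigma, preserve_range=True)
        reference = gaussian_blur(reference, sigma=blur_sigma,
                                  preserve_range=True)
    if noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, noise_sd, image.shape),
                        0.0, None)
    record = GroundTruthRecord(
        generator="two_phase_vesicle",
        params={"radius_px": radius_px, "i_lo": i_lo, "i_ld": i_ld,
                "noise_sd": noise_sd, "ring_width_px": ring_width_px,
                "blur_sigma": blur_sigma, "margin_px": margin_px,
                "line_endpoints": [[c, 0], [c, size - 1]]},
        seed=seed,
        expected={"percent_lo": 100.0 * i_lo / (i_lo + i_ld)})
    return image, reference, record


def generate_carpet(config: SimulationConfig, n_pixels: int = 52,
                    pixel_size_nm: float = 100.0,
                    scan_frequency: float = 2081.0,
                    bleach_tau_s: Optional[float] = None
                    ) -> Tuple[SFCSCarpet, GroundTruthRecord]:
    """Scanning-FCS carpet from one simulation run.

    The detection spot is evaluated at ``n_pixels`` centers spaced
    ``pixel_size_nm`` along a horizontal line through the domain center,
    once per scan cycle (the nearest integer multiple of the simulation
    step to 1/scan_frequency). An optional multiplicative exponential
    photobleaching overlay exp(-t/bleach_tau_s) is applied at the detection
    stage, leaving the underlying diffusion untouched, to exercise the
    bleach correction in isolation.
    """
    line_len = n_pixels * pixel_size_nm * 1e-3
    if line_len > config.domain_size:
        raise ConfigError(
            f"scan line ({line_len:.2f} um) does not fit inside the "
            f"{config.domain_size} um domain")
    sample_every = max(1, int(round(1.0 / (scan_frequency * config.dt))))
    eff_freq = 1.0 / (sample_every * config.dt)
    c = 0.5 * config.domain_size
    xs = c + (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * pixel_size_nm * 1e-3
    spots = [(float(x), c) for x in xs]
    result = run_simulation(config, spots=spots, sample_every=sample_every)
    carpet_vals = result.intensities.T.copy()   # (pixels, cycles)
    if bleach_tau_s is not None:
        decay = np.exp(-result.times / bleach_tau_s)
        carpet_vals *= decay[None, :]
    carpet = SFCSCarpet(intensities=carpet_vals, scan_frequency=eff_freq,
                        pixel_size_nm=pixel_size_nm,
                        meta={"seed": config.seed, "mode": config.mode,
                              "bleach_tau_s": bleach_tau_s})
    record = GroundTruthRecord(
        generator="carpet",
        params={"config": config.to_dict(), "n_pixels": n_pixels,
                "pixel_size_nm": pixel_size_nm,
                "scan_frequency": scan_frequency,
                "effective_scan_frequency": eff_freq,
                "bleach_tau_s": bleach_tau_s},
        seed=config.seed,
        expected={"d_um2_per_s": config.d_in, "mode": config.mode,
                  "n_cycles": n_scan_cycles(config.duration, eff_freq)})
    return carpet, record
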