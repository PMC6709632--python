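"""Particle-based Monte Carlo simulation of hindered lipid diffusion.

Simulates 2D Brownian motion of membrane molecules in three modes:

``free``
    unrestricted Brownian motion with microscopic diffusion coefficient
    ``d_in``; per-axis displacement per step is N(0, sqrt(2*d_in*dt)).
``trapped``
    a two-state Markov model of transient complex formation: each mobile
    particle becomes immobile with probability ``p_trap`` per step and each
    trapped particle is released with probability ``p_untrap``. Trapped
    particles stay fluorescent and contribute to the detected intensity.
``hop``
    meshwork-compartmentalized (hop) diffusion: the domain is tiled by a
    Voronoi mesh with characteristic cell size ``mesh_size_nm`` (the square
    root of the mean cell area) and a proposed step that would cross a
    compartment boundary is only accepted with probability ``p_hop``,
    otherwise the particle bounces (stays put for that step).

A Gaussian observation spot placed in the domain converts particle
positions into an apparent fluorescence intensity, sampled every time step
(or every ``sample_every`` steps for scanned readout). The default domain
is a periodic square (torus) of side ``domain_size``; an optional circular
domain with antipodal re-entry is available via ``domain_shape='circle'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "ParticleEnsemble",
    "VoronoiMesh",
    "SimulationResult",
    "build_voronoi_mesh",
    "detect_intensity",
    "step_free",
    "step_trapped",
    "step_hop",
    "run_simulation",
    "fwhm_to_waist",
]

_MODES = ("free", "trapped", "hop")
_SHAPES = ("square", "circle")
_CONVENTIONS = ("fwhm", "waist")


def fwhm_to_waist(fwhm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to the 1/e^2 radius w0."""
    return fwhm / math.sqrt(2.0 * math.log(2.0))


@dataclass
class SimulationConfig:
    """Parameters of one Monte Carlo run.

    Defaults reproduce the reference simulation conditions: 350 particles
    moving at 1 um^2/s in 1 us steps for 20 s on a 3 um domain, probed by a
    250 nm (FWHM) Gaussian spot; trap/untrap probabilities 5e-5 per step in
    trapped mode; 110 nm mesh with 5% boundary-crossing probability in hop
    mode.
    """

    n_particles: int = 350
    d_in: float = 1.0            # um^2/s
    dt: float = 1e-6             # s
    duration: float = 20.0       # s
    domain_size: float = 3.0     # um (side or diameter)
    domain_shape: str = "square"
    spot_size_nm: float = 250.0
    spot_convention: str = "fwhm"
    mode: str = "free"
    p_trap: float = 5e-5
    p_untrap: float = 5e-5
    p_hop: float = 0.05
    mesh_size_nm: float = 110.0
    seed: int = 0
    photon_noise: bool = False
    count_rate_hz: float = 0.0   # mean counts/s for a particle at the spot center
    max_samples: int = 60_000_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        if not (self.d_in >= 0.0):
            raise ConfigError("d_in must be >= 0")
        if not (self.dt > 0.0):
            raise ConfigError("dt must be > 0")
        if not (self.duration > 0.0):
            raise ConfigError("duration must be > 0")
        if not (self.domain_size > 0.0):
            raise ConfigError("domain_size must be > 0")
        if self.domain_shape not in _SHAPES:
            raise ConfigError(f"domain_shape must be one of {_SHAPES}")
        if self.spot_convention not in _CONVENTIONS:
            raise ConfigError(f"spot_convention must be one of {_CONVENTIONS}")
        if not (self.spot_size_nm > 0.0):
            raise ConfigError("spot_size_nm must be > 0")
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}")
        for name in ("p_trap", "p_untrap", "p_hop"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.mode == "hop":
            if not (self.mesh_size_nm > 0.0):
                raise ConfigError("mesh_size_nm must be > 0 in hop mode")
            if self.mesh_size_nm * 1e-3 >= self.domain_size:
                raise ConfigError("mesh_size_nm must be smaller than the domain")
        if self.photon_noise and not (self.count_rate_hz > 0.0):
            raise ConfigError("photon_noise requires a positive count_rate_hz")

    @property
    def w0_um(self) -> float:
        """1/e^2 Gaussian spot radius in um, per the configured convention."""
        size_um = self.spot_size_nm * 1e-3
        if self.spot_convention == "fwhm":
            return fwhm_to_waist(size_um)
        return size_um

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class VoronoiMesh:
    """Voronoi partition of the domain, rasterized for O(1) cell lookup.

    Cell membership is the nearest-seed rule, evaluated on a raster grid
    whose resolution (``mesh/64`` by default) is well below the rms step
    length, so boundary placement error is negligible against the physics.
    On the torus the nearest-seed distance is periodic. The raster is
    built lazily on first lookup.
    """

    seed_points: np.ndarray          # (n_seeds, 2) um
    domain_size: float               # um
    periodic: bool = True
    n_grid: Optional[int] = None
    _grid: Optional[np.ndarray] = None   # (n_grid, n_grid) int32 cell ids

    @property
    def n_cells(self) -> int:
        return len(self.seed_points)

    @property
    def mean_cell_area(self) -> float:
        return self.domain_size ** 2 / self.n_cells

    @property
    def characteristic_size_um(self) -> float:
        """sqrt(mean cell area), the characteristic mesh size."""
        return math.sqrt(self.mean_cell_area)

    def raster(self) -> np.ndarray:
        """Rasterized nearest-seed cell ids (built on first use)."""
        if self._grid is None:
            n_grid = self.n_grid
            if n_grid is None:
                approx_mesh = self.domain_size / max(
                    1.0, math.sqrt(self.n_cells))
                n_grid = int(min(4096, max(
                    64, round(64 * self.domain_size / approx_mesh))))
            if self.periodic:
                offs = np.array([(i, j) for i in (-1, 0, 1)
                                 for j in (-1, 0, 1)],
                                dtype=float) * self.domain_size
                tiled = (self.seed_points[None, :, :]
                         + offs[:, None, :]).reshape(-1, 2)
            else:
                tiled = self.seed_points
            tree = cKDTree(tiled)
            centers = (np.arange(n_grid) + 0.5) * (self.domain_size / n_grid)
            gx, gy = np.meshgrid(centers, centers, indexing="ij")
            _, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]),
                                workers=-1)
            self._grid = (idx % self.n_cells).astype(np.int32).reshape(
                n_grid, n_grid)
        return self._grid

    def cell_of(self, x, y) -> np.ndarray:
        """Map positions (um, inside the domain) to cell indices."""
        grid = self.raster()
        n_grid = grid.shape[0]
        inv = n_grid / self.domain_size
        gi = np.minimum((np.asarray(x) * inv).astype(np.int64), n_grid - 1)
        gj = np.minimum((np.asarray(y) * inv).astype(np.int64), n_grid - 1)
        return grid[gi, gj]

    @classmethod
    def from_points(cls, seed_points, domain_size, periodic=True,
                    n_grid=None) -> "VoronoiMesh":
        seed_points = np.atleast_2d(np.asarray(seed_points, dtype=float))
        return cls(seed_points=seed_points, domain_size=domain_size,
                   periodic=periodic, n_grid=n_grid)


def build_voronoi_mesh(domain_size: float, mesh_size_um: float,
                       rng: np.random.Generator) -> VoronoiMesh:
    """Draw a Voronoi mesh with characteristic cell size ``mesh_size_um``.

    Seed points follow a uniform Poisson process with density
    1/mesh_size^2, so sqrt(mean cell area) matches the requested size within
    Monte Carlo sampling error.
    """
    if not (0.0 < mesh_size_um < domain_size):
        raise ConfigError("mesh size must be positive and below the domain size")
    expected = (domain_size / mesh_size_um) ** 2
    n_seeds = int(rng.poisson(expected))
    if n_seeds < 4:
        raise ConfigError(
            f"mesh density yields only {n_seeds} seeds (< 4); "
            "increase the domain or decrease the mesh size")
    seeds = rng.random((n_seeds, 2)) * domain_size
    return VoronoiMesh.from_points(seeds, domain_size)


@dataclass
class ParticleEnsemble:
    """Evolving state of the particle system.

    ``x, y`` are wrapped into the domain; ``ux, uy`` accumulate unwrapped
    displacements so mean-squared displacement remains well defined on the
    torus.
    """

    x: np.ndarray
    y: np.ndarray
    trapped: np.ndarray              # uint8 flags
    time: float = 0.0
    ux: np.ndarray = None
    uy: np.ndarray = None

    def __post_init__(self):
        if self.ux is None:
            self.ux = np.zeros_like(self.x)
        if self.uy is None:
            self.uy = np.zeros_like(self.y)

    @property
    def n(self) -> int:
        return len(self.x)

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(self.x.copy(), self.y.copy(),
                                self.trapped.copy(), self.time,
                                self.ux.copy(), self.uy.copy())

    @classmethod
    def initialize(cls, config: SimulationConfig,
                   rng: np.random.Generator) -> "ParticleEnsemble":
        n, L = config.n_particles, config.domain_size
        if config.domain_shape == "square":
            pos = rng.random((n, 2)) * L
        else:
            pos = np.empty((n, 2))
            c = R = 0.5 * L
            filled = 0
            while filled < n:
                cand = rng.random((2 * (n - filled), 2)) * L
                keep = ((cand[:, 0] - c) ** 2 + (cand[:, 1] - c) ** 2) <= R * R
                take = cand[keep][: n - filled]
                pos[filled:filled + len(take)] = take
                filled += len(take)
        return cls(x=pos[:, 0].copy(), y=pos[:, 1].copy(),
                   trapped=np.zeros(n, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Reference (numpy) steppers: one step at a time, drawing from the supplied
# generators in a fixed order. These define the update rules; run_simulation
# executes the bit-identical numba kernels.
# ---------------------------------------------------------------------------

def _wrap_positions(nx, ny, config):
    L = config.domain_size
    if config.domain_shape == "square":
        return nx % L, ny % L
    c = R = 0.5 * L
    dx, dy = nx - c, ny - c
    r2 = dx * dx + dy * dy
    out = r2 > R * R
    if np.any(out):
        r = np.sqrt(r2[out])
        f = (2.0 * R - r) / r
        nx = nx.copy()
        ny = ny.copy()
        nx[out] = c - dx[out] * f
        ny[out] = c - dy[out] * f
    return nx, ny


def step_free(ensemble: ParticleEnsemble, config: SimulationConfig,
              rng: np.random.Generator) -> ParticleEnsemble:
    """Advance every untrapped particle by one free-diffusion step."""
    if config.d_in < 0 or config.dt <= 0:
        raise ConfigError("d_in must be >= 0 and dt > 0")
    normals = rng.standard_normal((ensemble.n, 2))
    return _apply_displacement(ensemble, config, normals,
                               mobile=ensemble.trapped == 0)


def _apply_displacement(ensemble, config, normals, mobile):
    sigma = math.sqrt(2.0 * config.d_in * config.dt)
    dx = sigma * normals[:, 0]
    dy = sigma * normals[:, 1]
    nx, ny = _wrap_positions(ensemble.x + dx, ensemble.y + dy, config)
    out = ensemble.copy()
    out.x[mobile] = nx[mobile]
    out.y[mobile] = ny[mobile]
    out.ux[mobile] += dx[mobile]
    out.uy[mobile] += dy[mobile]
    out.time = ensemble.time + config.dt
    return out


def step_trapped(ensemble: ParticleEnsemble, config: SimulationConfig,
                 rng: np.random.Generator,
                 rng_state: Optional[np.random.Generator] = None
                 ) -> ParticleEnsemble:
    """Trap/untrap each particle, then move the mobile ones.

    State transitions are evaluated before displacement, so a particle
    released this step moves this step. ``rng_state`` supplies the Bernoulli
    stream; keeping it separate from the displacement stream makes the
    p_trap=0 limit bit-identical to :func:`step_free` at equal seed.
    """
    if rng_state is None:
        rng_state = rng
    u = rng_state.random(ensemble.n)
    trapped = ensemble.trapped.copy()
    release = (trapped == 1) & (u < config.p_untrap)
    capture = (trapped == 0) & (u < config.p_trap)
    trapped[release] = 0
    trapped[capture] = 1
    normals = rng.standard_normal((ensemble.n, 2))
    tmp = ParticleEnsemble(ensemble.x, ensemble.y, trapped, ensemble.time,
                           ensemble.ux, ensemble.uy)
    return _apply_displacement(tmp, config, normals, mobile=trapped == 0)


def step_hop(ensemble: ParticleEnsemble, config: SimulationConfig,
             mesh: VoronoiMesh, rng: np.random.Generator,
             rng_state: Optional[np.random.Generator] = None
             ) -> ParticleEnsemble:
    """Propose a free step; reject boundary crossings with prob. 1 - p_hop."""
    if rng_state is None:
        rng_state = rng
    u = rng_state.random(ensemble.n)
    normals = rng.standard_normal((ensemble.n, 2))
    sigma = math.sqrt(2.0 * config.d_in * config.dt)
    dx = sigma * normals[:, 0]
    dy = sigma * normals[:, 1]
    nx, ny = _wrap_positions(ensemble.x + dx, ensemble.y + dy, config)
    old_cell = mesh.cell_of(ensemble.x, ensemble.y)
    new_cell = mesh.cell_of(nx, ny)
    accept = (old_cell == new_cell) | (u < config.p_hop)
    out = ensemble.copy()
    out.x[accept] = nx[accept]
    out.y[accept] = ny[accept]
    out.ux[accept] += dx[accept]
    out.uy[accept] += dy[accept]
    out.time = ensemble.time + config.dt
    return out


def detect_intensity(ensemble: ParticleEnsemble, spot_center,
                     config: SimulationConfig) -> float:
    """Apparent fluorescence: sum of Gaussian-spot weights over particles.

    I = sum_i exp(-2 r_i^2 / w0^2) with r_i the (minimal-image on the torus)
    distance to the spot center and w0 the 1/e^2 radius. A particle exactly
    at the center contributes 1; trapped particles contribute like any other.
    """
    sx, sy = spot_center
    dx = ensemble.x - sx
    dy = ensemble.y - sy
    if config.domain_shape == "square":
        L = config.domain_size
        dx -= L * np.round(dx / L)
        dy -= L * np.round(dy / L)
    w0 = config.w0_um
    return float(np.sum(np.exp(-2.0 * (dx * dx + dy * dy) / (w0 * w0))))


# ---------------------------------------------------------------------------
# Fast path
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`."""

    times: np.ndarray                 # sample times (s)
    intensities: np.ndarray           # (n_samples, n_spots)
    trapped_counts: np.ndarray        # trapped particles at each sample
    config: SimulationConfig
    mesh: Optional[VoronoiMesh] = None
    traj_times: Optional[np.ndarray] = None
    traj_x: Optional[np.ndarray] = None   # unwrapped, (n_snapshots, n)
    traj_y: Optional[np.ndarray] = None
    final_ensemble: Optional[ParticleEnsemble] = None

    @property
    def trace(self):
        from .correlator import IntensityTrace
        dt_sample = float(self.times[1] - self.times[0]) if len(self.times) > 1 \
            else self.config.dt
        return IntensityTrace(values=self.intensities[:, 0],
                              dt=dt_sample,
                              meta={"seed": self.config.seed,
                                    "mode": self.config.mode})

    def msd(self):
        """Ensemble MSD (um^2) at each trajectory snapshot, relative to t=0."""
        if self.traj_x is None:
            raise ConfigError("run_simulation was called without trajectories")
        dx = self.traj_x - self.traj_x[0]
        dy = self.traj_y - self.traj_y[0]
        return self.traj_times, (dx * dx + dy * dy).mean(axis=1)


def run_simulation(config: SimulationConfig,
                   mesh: Optional[VoronoiMesh] = None,
                   spots=None,
                   sample_every: int = 1,
                   record_trajectories: bool = False,
                   traj_interval: Optional[int] = None) -> SimulationResult:
    """Run the full Monte Carlo simulation.

    Parameters
    ----------
    mesh:
        Voronoi mesh for hop mode; built from the config seed when omitted.
    spots:
        Sequence of (x, y) spot centers in um; defaults to the domain center.
    sample_every:
        Record the intensity every this many steps (1 = every step, the
        point-FCS readout; >1 emulates a scanned line sampled once per cycle).
    record_trajectories:
        Snapshot unwrapped particle coordinates every ``traj_interval`` steps
        (default: every ``sample_every`` steps) for MSD analysis.
    """
    config.validate()
    n = config.n_particles
    n_steps = config.n_steps
    if n_steps < 1:
        raise ConfigError("duration shorter than one time step")
    if sample_every < 1:
        raise ConfigError("sample_every must be >= 1")
    n_samples = n_steps // sample_every
    if spots is None:
        c = 0.5 * config.domain_size
        spots = [(c, c)]
    spots = np.asarray(spots, dtype=float)
    if n_samples * len(spots) > config.max_samples:
        raise ConfigError(
            f"run would produce {n_samples * len(spots)} samples, above the "
            f"max_samples guard ({config.max_samples}); shorten the duration, "
            "raise sample_every, or raise max_samples explicitly")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_disp, rng_state, rng_noise, rng_mesh = [
        np.random.default_rng(s) for s in ss.spawn(5)]

    ens = ParticleEnsemble.initialize(config, rng_init)
    mode = {"free": _kernels.MODE_FREE, "trapped": _kernels.MODE_TRAPPED,
            "hop": _kernels.MODE_HOP}[config.mode]
    shape = {"square": _kernels.SHAPE_SQUARE,
             "circle": _kernels.SHAPE_CIRCLE}[config.domain_shape]
    if mode == _kernels.MODE_HOP:
        if mesh is None:
            mesh = build_voronoi_mesh(config.domain_size,
                                      config.mesh_size_nm * 1e-3, rng_mesh)
        grid = mesh.raster()
    else:
        grid = np.zeros((1, 1), dtype=np.int32)

    sigma = math.sqrt(2.0 * config.d_in * config.dt)
    w0 = config.w0_um
    out = np.empty((n_samples, len(spots)))
    out_trapped = np.zeros(n_samples, dtype=np.int64)

    if record_trajectories:
        if traj_interval is None:
            traj_interval = sample_every
        n_snap = n_steps // traj_interval + 1
        traj_x = np.empty((n_snap, n))
        traj_y = np.empty((n_snap, n))
        traj_t = np.arange(n_snap) * (traj_interval * config.dt)
        traj_x[0] = ens.ux
        traj_y[0] = ens.uy
        chunk = traj_interval
    else:
        traj_x = traj_y = traj_t = None
        chunk = max(1, min(8192, int(4e6 / max(1, n))))

    row = 0
    step = 0
    snap = 1
    need_u = mode != _kernels.MODE_FREE
    dummy_u = np.empty((1, 1))
    while step < n_steps:
        c_steps = min(chunk, n_steps - step)
        normals = rng_disp.standard_normal((c_steps, n, 2))
        uniforms = rng_state.random((c_steps, n)) if need_u else dummy_u
        row = _kernels.run_chunk(
            ens.x, ens.y, ens.ux, ens.uy, ens.trapped,
            normals, uniforms,
            sigma, config.domain_size, shape, mode,
            config.p_trap, config.p_untrap, config.p_hop,
            grid, grid.shape[0],
            spots[:, 0].copy(), spots[:, 1].copy(), -2.0 / (w0 * w0),
            out, out_trapped, sample_every, step, row)
        step += c_steps
        if record_trajectories and step % traj_interval == 0 and snap < n_snap:
            traj_x[snap] = ens.ux
            traj_y[snap] = ens.uy
            snap += 1
    ens.time = n_steps * config.dt

    if config.photon_noise:
        dt_sample = config.dt * sample_every
        out = rng_noise.poisson(out * config.count_rate_hz * dt_sample)
        out = out.astype(float)

    times = np.arange(1, n_samples + 1) * (config.dt * sample_every)
    return SimulationResult(times=times, intensities=out,
                            trapped_counts=out_trapped, config=config,
                            mesh=mesh, traj_times=traj_t,
                            traj_x=traj_x, traj_y=traj_y,
                            final_ensemble=ens)
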