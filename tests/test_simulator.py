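"""Monte Carlo simulator: update rules, mesh, detection, reproducibility."""

import math

import numpy as np
import pytest

from memfcs.errors import ConfigError
from memfcs.simulator import (ParticleEnsemble, SimulationConfig, VoronoiMesh,
                              build_voronoi_mesh, detect_intensity, step_free,
                              step_hop, step_trapped, run_simulation,
                              fwhm_to_waist)


def _ensemble(x, y, trapped=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if trapped is None:
        trapped = np.zeros(len(x), dtype=np.uint8)
    return ParticleEnsemble(x=x, y=y, trapped=np.asarray(trapped,
                                                         dtype=np.uint8))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"dt": -1e-6}, {"dt": 0.0}, {"d_in": -1.0}, {"n_particles": 0},
        {"p_trap": 1.5}, {"p_hop": -0.1}, {"mode": "ballistic"},
        {"mode": "hop", "mesh_size_nm": 0.0},
        {"photon_noise": True, "count_rate_hz": 0.0},
        {"duration": -1.0}, {"spot_convention": "hwhm"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig.from_dict({"n_particle": 10})

    def test_defaults_are_study_conditions(self):
        cfg = SimulationConfig()
        assert (cfg.n_particles, cfg.dt, cfg.duration) == (350, 1e-6, 20.0)
        assert (cfg.domain_size, cfg.spot_size_nm) == (3.0, 250.0)
        assert cfg.p_trap == cfg.p_untrap == 5e-5
        assert (cfg.mesh_size_nm, cfg.p_hop) == (110.0, 0.05)

    def test_spot_conventions(self):
        fwhm = SimulationConfig(spot_size_nm=250, spot_convention="fwhm")
        waist = SimulationConfig(spot_size_nm=250, spot_convention="waist")
        assert fwhm.w0_um == pytest.approx(0.25 / math.sqrt(2 * math.log(2)))
        assert waist.w0_um == 0.25


class TestFreeStep:
    def test_zero_diffusion_is_identity(self):
        cfg = SimulationConfig(n_particles=10, d_in=0.0)
        ens = _ensemble(np.linspace(0.1, 2.9, 10), np.linspace(0.1, 2.9, 10))
        out = step_free(ens, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.x, ens.x)
        np.testing.assert_array_equal(out.y, ens.y)
        assert out.time == pytest.approx(cfg.dt)

    def test_step_sd_matches_closed_form(self):
        # sigma = sqrt(2 D dt) = sqrt(2e-6) ~ 1.414e-3 um for D=1, dt=1us
        cfg = SimulationConfig(n_particles=200_000)
        n = cfg.n_particles
        rng = np.random.default_rng(7)
        ens = _ensemble(np.full(n, 1.5), np.full(n, 1.5))
        out = step_free(ens, cfg, rng)
        sd = np.std(out.x - ens.x)
        assert sd == pytest.approx(math.sqrt(2e-6), rel=0.01)

    def test_msd_slope_recovers_d_in(self):
        # brute-force MSD oracle: MSD(t) = 4 D t in 2D
        cfg = SimulationConfig(n_particles=10_000, duration=0.01, seed=5)
        res = run_simulation(cfg, sample_every=2000,
                             record_trajectories=True, traj_interval=2000)
        t, msd = res.msd()
        d_hat = msd[-1] / (4.0 * t[-1])
        se = cfg.d_in / math.sqrt(cfg.n_particles)
        assert abs(d_hat - cfg.d_in) < 3 * se
        # linearity: interior points consistent with the same slope
        slopes = msd[1:] / (4.0 * t[1:])
        assert np.all(np.abs(slopes - cfg.d_in) < 5 * se * np.sqrt(t[-1] / t[1:]))


class TestTrappedStep:
    def test_p_trap_zero_identical_to_free(self):
        free = run_simulation(SimulationConfig(
            n_particles=50, duration=2e-3, seed=9))
        trap = run_simulation(SimulationConfig(
            n_particles=50, duration=2e-3, seed=9, mode="trapped",
            p_trap=0.0, p_untrap=0.0))
        np.testing.assert_array_equal(free.intensities, trap.intensities)

    @pytest.mark.parametrize("p_trap,p_untrap,expected", [
        (5e-4, 5e-4, 0.5),
        (2e-4, 6e-4, 0.25),
    ])
    def test_stationary_trapped_fraction(self, p_trap, p_untrap, expected):
        # two-state Markov chain: stationary fraction p_trap/(p_trap+p_untrap)
        cfg = SimulationConfig(n_particles=2000, duration=0.05, seed=3,
                               mode="trapped", p_trap=p_trap,
                               p_untrap=p_untrap)
        res = run_simulation(cfg, sample_every=100)
        frac = res.trapped_counts[len(res.trapped_counts) // 2:] \
            / cfg.n_particles
        assert frac.mean() == pytest.approx(expected, abs=0.03)

    def test_effective_d_is_mobile_fraction_times_d(self):
        # equal trap/untrap rates -> mobile fraction 1/2 -> slope/4 ~ 0.5
        cfg = SimulationConfig(n_particles=1000, duration=0.3, seed=11,
                               mode="trapped")
        res = run_simulation(cfg, sample_every=10_000,
                             record_trajectories=True, traj_interval=10_000)
        t, msd = res.msd()
        half = len(t) // 2
        slope = np.polyfit(t[half:], msd[half:], 1)[0]
        assert slope / 4.0 == pytest.approx(0.5, abs=0.07)

    def test_trapped_particles_do_not_move(self):
        cfg = SimulationConfig(n_particles=200, mode="trapped", p_trap=0.5,
                               p_untrap=0.0)
        ens = ParticleEnsemble.initialize(cfg, np.random.default_rng(1))
        rng, rng_state = (np.random.default_rng(2), np.random.default_rng(3))
        prev = ens
        for _ in range(5):
            cur = step_trapped(prev, cfg, rng, rng_state)
            frozen = (prev.trapped == 1) & (cur.trapped == 1)
            np.testing.assert_array_equal(cur.x[frozen], prev.x[frozen])
            prev = cur
        assert prev.trapped.sum() > 0


class TestHopStep:
    def test_p_hop_one_equals_free(self):
        free = run_simulation(SimulationConfig(
            n_particles=60, duration=2e-3, seed=13))
        hop = run_simulation(SimulationConfig(
            n_particles=60, duration=2e-3, seed=13, mode="hop", p_hop=1.0))
        np.testing.assert_allclose(hop.intensities, free.intensities,
                                   rtol=1e-12)

    def test_p_hop_zero_confines_msd(self):
        # full confinement: MSD plateaus at the compartment scale
        cfg = SimulationConfig(n_particles=500, duration=0.1, seed=17,
                               mode="hop", p_hop=0.0)
        res = run_simulation(cfg, sample_every=5000,
                             record_trajectories=True, traj_interval=5000)
        t, msd = res.msd()
        mesh2 = (cfg.mesh_size_nm * 1e-3) ** 2
        assert msd[-1] < 4.0 * mesh2          # bounded by compartment scale
        assert msd[-1] < 0.02 * 4 * cfg.d_in * t[-1]   # far below free MSD
        assert msd[-1] / msd[len(msd) // 2] < 1.5       # plateaued

    def test_hop_slows_long_time_diffusion(self):
        cfg = SimulationConfig(n_particles=500, duration=0.2, seed=19,
                               mode="hop")
        res = run_simulation(cfg, sample_every=10_000,
                             record_trajectories=True, traj_interval=10_000)
        t, msd = res.msd()
        d_app = msd[-1] / (4.0 * t[-1])
        assert d_app < 0.9 * cfg.d_in


class TestVoronoiMesh:
    def test_single_seed_maps_everything_to_cell_zero(self):
        mesh = VoronoiMesh.from_points([[1.5, 1.5]], 3.0, n_grid=64)
        xs = np.linspace(0.01, 2.99, 10)
        assert np.all(mesh.cell_of(xs, xs[::-1]) == 0)

    def test_expected_cell_count(self):
        # density 1/mesh^2 -> ~ 9 / 0.0121 ~ 744 cells on a 3 um domain
        rng = np.random.default_rng(23)
        mesh = build_voronoi_mesh(3.0, 0.110, rng)
        assert abs(mesh.n_cells - 744) < 5 * math.sqrt(744)

    def test_characteristic_size_over_meshes(self):
        rng = np.random.default_rng(29)
        sizes = [build_voronoi_mesh(3.0, 0.110, rng).characteristic_size_um
                 for _ in range(20)]
        assert np.mean(sizes) == pytest.approx(0.110, rel=0.05)

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ConfigError):
            build_voronoi_mesh(3.0, 2.9, np.random.default_rng(0))

    def test_every_position_maps_to_one_cell(self):
        mesh = build_voronoi_mesh(3.0, 0.3, np.random.default_rng(31))
        pts = np.random.default_rng(1).random((500, 2)) * 3.0
        cells = mesh.cell_of(pts[:, 0], pts[:, 1])
        assert cells.shape == (500,)
        assert np.all((cells >= 0) & (cells < mesh.n_cells))


class TestDetection:
    def test_distant_particle_contributes_nothing(self):
        cfg = SimulationConfig(n_particles=1)
        ens = _ensemble([0.1], [0.1])
        assert detect_intensity(ens, (1.5, 1.5), cfg) < 1e-12

    def test_particle_at_center_gives_unit_peak(self):
        cfg = SimulationConfig(n_particles=1)
        ens = _ensemble([1.5], [1.5])
        assert detect_intensity(ens, (1.5, 1.5), cfg) == pytest.approx(1.0)

    def test_half_maximum_at_half_fwhm(self):
        cfg = SimulationConfig(n_particles=1)
        ens = _ensemble([1.5 + 0.125], [1.5])  # FWHM/2 = 125 nm off center
        assert detect_intensity(ens, (1.5, 1.5), cfg) == pytest.approx(0.5)

    def test_intensity_is_additive(self):
        cfg = SimulationConfig(n_particles=3)
        ens = _ensemble([1.5, 1.5, 1.5], [1.5, 1.5, 1.5])
        assert detect_intensity(ens, (1.5, 1.5), cfg) == pytest.approx(3.0)


class TestRunSimulation:
    def test_trace_length_is_duration_over_dt(self):
        cfg = SimulationConfig(n_particles=5, dt=1e-4, duration=1e-3)
        res = run_simulation(cfg)
        assert len(res.trace) == 10

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_particles=40, duration=5e-3, seed=37,
                               mode="trapped", p_trap=1e-3, p_untrap=1e-3)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_memory_guard(self):
        cfg = SimulationConfig(n_particles=5, max_samples=1000)
        with pytest.raises(ConfigError):
            run_simulation(cfg)

    def test_positions_stay_inside_domain(self):
        cfg = SimulationConfig(n_particles=100, duration=5e-3, seed=41,
                               d_in=50.0)
        res = run_simulation(cfg)
        ens = res.final_ensemble
        L = cfg.domain_size
        assert ens.n == cfg.n_particles
        assert np.all((ens.x >= 0) & (ens.x < L))
        assert np.all((ens.y >= 0) & (ens.y < L))

    def test_photon_noise_yields_integer_counts(self):
        cfg = SimulationConfig(n_particles=100, duration=2e-3, seed=43,
                               photon_noise=True, count_rate_hz=5e5)
        res = run_simulation(cfg)
        assert np.all(res.intensities == np.round(res.intensities))

    def test_circular_domain_keeps_particles_inside(self):
        cfg = SimulationConfig(n_particles=100, duration=5e-3, seed=47,
                               d_in=50.0, domain_shape="circle")
        res = run_simulation(cfg)
        ens = res.final_ensemble
        r = np.hypot(ens.x - 1.5, ens.y - 1.5)
        assert np.all(r <= 1.5 + 1e-12)


class TestKernelMatchesReferenceSteppers:
    """The numba fast path must reproduce the numpy reference steppers
    exactly when both consume the same random streams."""

    @pytest.mark.parametrize("mode", ["free", "trapped", "hop"])
    def test_trace_matches_stepwise_reference(self, mode):
        cfg = SimulationConfig(n_particles=30, dt=1e-5, duration=2e-3,
                               seed=53, mode=mode, d_in=2.0,
                               p_trap=0.05, p_untrap=0.05,
                               mesh_size_nm=300.0)
        fast = run_simulation(cfg)

        ss = np.random.SeedSequence(cfg.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
        rng_init, rng_disp, rng_state, _, rng_mesh = rngs
        ens = ParticleEnsemble.initialize(cfg, rng_init)
        mesh = build_voronoi_mesh(cfg.domain_size, cfg.mesh_size_nm * 1e-3,
                                  rng_mesh) if mode == "hop" else None
        center = (1.5, 1.5)
        intensities = []
        for _ in range(cfg.n_steps):
            if mode == "free":
                ens = step_free(ens, cfg, rng_disp)
            elif mode == "trapped":
                ens = step_trapped(ens, cfg, rng_disp, rng_state)
            else:
                ens = step_hop(ens, cfg, mesh, rng_disp, rng_state)
            intensities.append(detect_intensity(ens, center, cfg))
        np.testing.assert_allclose(fast.intensities[:, 0], intensities,
                                   rtol=1e-10, atol=1e-12)
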