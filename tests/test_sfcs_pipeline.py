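"""Scanning-FCS pipeline: crop, bleach correction, per-pixel analysis."""

import numpy as np
import pytest

from memfcs.errors import ConfigError
from memfcs.fcs_models import SpotCalibration
from memfcs.sfcs_pipeline import (SFCSCarpet, analyze_carpet, bleach_correct,
                                  crop_initial)
from memfcs.simulator import SimulationConfig, run_simulation
from memfcs.synthetic_data import generate_carpet

CALIB = SpotCalibration.from_fwhm(250.0)


def _noise_carpet(n_pixels=4, n_cycles=5000, seed=0):
    rng = np.random.default_rng(seed)
    return SFCSCarpet(rng.poisson(50.0, (n_pixels, n_cycles)).astype(float),
                      scan_frequency=2000.0)


@pytest.fixture(scope="module")
def line_trace():
    """Free-diffusion intensity sampled at the line-scan cadence (~2 kHz)."""
    cfg = SimulationConfig(n_particles=350, dt=1e-5, duration=15.0, seed=501)
    return run_simulation(cfg, sample_every=48).trace


@pytest.fixture(scope="module")
def full_carpet():
    """One canonical-length (40 s) free-diffusion carpet with ground truth.

    Domain enlarged to 4 um to fit a 2.4 um scan line; the particle count
    keeps the default area density (620/16 = 350/9 per um^2).
    """
    cfg = SimulationConfig(n_particles=620, dt=1e-5, duration=40.0,
                           domain_size=4.0, seed=601)
    return generate_carpet(cfg, n_pixels=24)


class TestCrop:
    def test_zero_crop_is_identity(self):
        carpet = _noise_carpet()
        out = crop_initial(carpet, 0.0)
        np.testing.assert_array_equal(out.intensities, carpet.intensities)

    def test_crop_arithmetic(self):
        # the reference acquisition: 50 s at 2081 Hz, first 10 s cropped
        carpet = SFCSCarpet(np.ones((2, 104_050)), scan_frequency=2081.0)
        out = crop_initial(carpet, 10.0)
        assert out.n_cycles == 40 * 2081

    def test_result_independent_of_cropped_samples(self):
        carpet = _noise_carpet(seed=1)
        modified = SFCSCarpet(carpet.intensities.copy(),
                              carpet.scan_frequency)
        modified.intensities[:, :1000] = 999.0
        a = crop_initial(carpet, 0.5)
        b = crop_initial(modified, 0.5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_crop_beyond_duration_rejected(self):
        with pytest.raises(ConfigError):
            crop_initial(_noise_carpet(), 10.0)


class TestBleachCorrect:
    def test_constant_trace_exactly_unchanged(self):
        carpet = SFCSCarpet(np.full((2, 4000), 80.0), scan_frequency=2000.0)
        out = bleach_correct(carpet, 1.0)
        np.testing.assert_allclose(out.intensities, carpet.intensities,
                                   rtol=1e-12)

    def test_stationary_trace_nearly_unchanged(self):
        carpet = _noise_carpet(n_cycles=20_000, seed=2)
        out = bleach_correct(carpet, 5.0)
        np.testing.assert_allclose(out.intensities, carpet.intensities,
                                   rtol=0.02, atol=0.5)
        np.testing.assert_allclose(out.intensities.mean(axis=1),
                                   carpet.intensities.mean(axis=1),
                                   rtol=1e-12)

    def test_exponential_bleach_flattened(self):
        rng = np.random.default_rng(3)
        n = 20000
        t = np.arange(n) / 2000.0
        base = rng.poisson(100.0, n).astype(float)
        carpet = SFCSCarpet((base * np.exp(-t / 20.0))[None, :],
                            scan_frequency=2000.0)
        out = bleach_correct(carpet, 2.0)
        v = out.intensities[0]
        slope = np.polyfit(t, v, 1)[0]
        raw_slope = np.polyfit(t, carpet.intensities[0], 1)[0]
        assert abs(slope) < 0.05 * abs(raw_slope)

    def test_mean_preserved_to_machine_precision(self):
        rng = np.random.default_rng(4)
        n = 10000
        decay = np.exp(-np.arange(n) / 4000.0)
        carpet = SFCSCarpet((rng.random((3, n)) + 1.0) * decay[None, :],
                            scan_frequency=2000.0)
        out = bleach_correct(carpet, 1.0)
        np.testing.assert_allclose(out.intensities.mean(axis=1),
                                   carpet.intensities.mean(axis=1),
                                   rtol=1e-9)

    def test_zero_trend_pixel_flagged(self):
        carpet = _noise_carpet(n_pixels=3, seed=5)
        carpet.intensities[1, :] = 0.0
        carpet.intensities[1, :10] = 1.0
        out = bleach_correct(carpet, 0.5)
        assert 1 in out.meta["bleach_flagged_pixels"]

    def test_window_longer_than_carpet_rejected(self):
        with pytest.raises(ConfigError):
            bleach_correct(_noise_carpet(n_cycles=100), 60.0)


class TestAnalyzeCarpet:
    def test_homogeneous_carpet_spread_is_sampling_only(self, line_trace):
        # every pixel carries the same signal -> identical fits
        carpet = SFCSCarpet(np.tile(line_trace.values, (6, 1)),
                            scan_frequency=1.0 / line_trace.dt)
        res = analyze_carpet(carpet, calibration=CALIB, n_bootstrap=0)
        assert res.n_converged == 6
        cv = res.transit_times_ms.std() / res.transit_times_ms.mean()
        assert cv < 1e-9

    def test_subcarpet_equals_subset_of_full_result(self, line_trace):
        full = SFCSCarpet(np.tile(line_trace.values, (4, 1)),
                          scan_frequency=1.0 / line_trace.dt)
        sub = SFCSCarpet(full.intensities[:2].copy(), full.scan_frequency)
        a = analyze_carpet(full, calibration=CALIB, n_bootstrap=2, seed=9)
        b = analyze_carpet(sub, calibration=CALIB, n_bootstrap=2, seed=9)
        np.testing.assert_allclose(b.transit_times_ms,
                                   a.transit_times_ms[:2], rtol=1e-12)
        assert b.fits[0].bootstrap_sd == a.fits[0].bootstrap_sd

    def test_two_region_carpet_is_bimodal(self, line_trace):
        # Brownian time-dilation: relabelling a D=1 trace with a 2x longer
        # sampling interval is statistically a D=0.5 trace, so fast pixels
        # (trace decimated by 2) and slow pixels (raw trace at the doubled
        # interval) have transit times exactly a factor 2 apart.
        fast_vals = line_trace.values[::2]
        slow_vals = line_trace.values[:len(fast_vals)]
        vals = np.vstack([np.tile(fast_vals, (4, 1)),
                          np.tile(slow_vals, (4, 1))])
        carpet = SFCSCarpet(vals, scan_frequency=0.5 / line_trace.dt)
        res = analyze_carpet(carpet, calibration=CALIB, n_bootstrap=0)
        fast = np.median(res.transit_times_ms[:4])
        slow = np.median(res.transit_times_ms[4:])
        assert 1.6 < slow / fast < 2.5

    def test_pooled_cpm_matches_single_spot_product(self, line_trace):
        carpet = SFCSCarpet(np.tile(line_trace.values, (4, 1)),
                            scan_frequency=1.0 / line_trace.dt)
        res = analyze_carpet(carpet, calibration=CALIB, n_bootstrap=0)
        fit = res.fits[0]
        expected = line_trace.mean_rate * fit.g0
        assert res.cpm.mean() == pytest.approx(expected, rel=0.10)


class TestFullSyntheticCarpet:
    def test_free_carpet_recovers_d_and_is_homogeneous(self, full_carpet):
        # one 40-s acquisition: pixel estimates share the same particles,
        # so the pooled median carries the single-run low-frequency noise
        # (~10%); the tolerance is set at twice that
        carpet, rec = full_carpet
        res = analyze_carpet(carpet, calibration=CALIB, n_bootstrap=0)
        ds = np.array([f.d[0] for f, q in zip(res.fits, res.qc)
                       if q.converged])
        assert np.median(ds) == pytest.approx(rec.expected["d_um2_per_s"],
                                              rel=0.20)
        cv = res.transit_times_ms.std() / res.transit_times_ms.mean()
        assert cv < 0.25

    def test_bleach_correction_restores_d(self, full_carpet):
        carpet, rec = full_carpet
        decay = np.exp(-np.arange(carpet.n_cycles) * carpet.line_period
                       / 30.0)
        bleached = SFCSCarpet(carpet.intensities * decay[None, :],
                              carpet.scan_frequency, carpet.pixel_size_nm)
        t = np.arange(bleached.n_cycles) * bleached.line_period
        corrected = bleach_correct(bleached, 18.0)
        # the corrected carpet is stationary again, the bleached one is not
        raw_slope = np.polyfit(t, bleached.intensities.mean(axis=0), 1)[0]
        cor_slope = np.polyfit(t, corrected.intensities.mean(axis=0), 1)[0]
        assert abs(cor_slope) < 0.05 * abs(raw_slope)
        res = analyze_carpet(corrected, calibration=CALIB, n_bootstrap=0)
        ds = np.array([f.d[0] for f, q in zip(res.fits, res.qc)
                       if q.converged])
        assert np.median(ds) == pytest.approx(rec.expected["d_um2_per_s"],
                                              rel=0.20)
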