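"""Shared fixtures: session-scoped simulation runs reused across tests.

The simulations use the reference study conditions (350 particles at
1 um^2/s with 1 us steps on a 3 um torus, 250 nm FWHM spot) with durations
of a few seconds; the intensity readout is taken every 4th step, still two
thousand times faster than the ~11 ms spot transit time.
"""

import numpy as np
import pytest

from memfcs.correlator import autocorrelate_multitau, restrict_lags
from memfcs.fcs_models import FCSModelSpec, SpotCalibration, fit_curve
from memfcs.simulator import SimulationConfig, run_simulation

CALIB = SpotCalibration.from_fwhm(250.0)
FREE_SEEDS = (101, 102, 103)


@pytest.fixture(scope="session")
def calibration():
    return CALIB


@pytest.fixture(scope="session")
def free_runs():
    """Free-diffusion runs at D_in = 1 um^2/s (three seeds, 4 s each)."""
    return [run_simulation(SimulationConfig(duration=4.0, seed=s),
                           sample_every=4)
            for s in FREE_SEEDS]


@pytest.fixture(scope="session")
def trapped_runs():
    """Trapped-diffusion runs (p_trap = p_untrap = 5e-5), 4 s each."""
    return [run_simulation(
        SimulationConfig(duration=4.0, seed=s, mode="trapped"),
        sample_every=4) for s in (201, 202, 203)]


@pytest.fixture(scope="session")
def hop_runs():
    """Hop-diffusion runs (110 nm mesh, p_hop = 0.05), 4 s each."""
    return [run_simulation(
        SimulationConfig(duration=4.0, seed=s, mode="hop"),
        sample_every=4) for s in (301, 302, 303)]


def fit_run(run, anomalous=False, tmax=0.1):
    """Correlate a run's trace and fit the 2D one-component model.

    The fit includes the free baseline G_inf: the closed periodic domain
    (conserved particle number) and the finite trace both depress the
    long-lag correlation by ~1% of G0 relative to the infinite-plane law.
    """
    curve = restrict_lags(autocorrelate_multitau(run.trace), tmax=tmax)
    return fit_curve(curve, FCSModelSpec(anomalous=anomalous, offset=True),
                     CALIB, mean_intensity=run.trace.mean_rate)


def fit_averaged(runs, anomalous=False, tmax=0.1):
    """Average the runs' correlation curves and fit once.

    Mirrors standard acquisition practice (and the per-condition averaging
    of repeat simulations): several few-second curves are averaged before
    fitting, which cancels most of the per-run low-frequency amplitude
    noise.
    """
    from memfcs.correlator import CorrelationCurve
    curves = [restrict_lags(autocorrelate_multitau(r.trace), tmax=tmax)
              for r in runs]
    mean_g = np.vstack([c.G for c in curves]).mean(axis=0)
    avg = CorrelationCurve(curves[0].lags, mean_g)
    return fit_curve(avg, FCSModelSpec(anomalous=anomalous, offset=True),
                     CALIB)


@pytest.fixture(scope="session")
def fitter():
    return fit_run


@pytest.fixture(scope="session")
def averaged_fitter():
    return fit_averaged
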