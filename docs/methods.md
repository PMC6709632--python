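# Methods

`memfcs` simulates lateral diffusion of fluorescent lipid analogues in a
membrane and analyses the resulting fluorescence fluctuations the way a
confocal FCS experiment would: point FCS on a single Gaussian spot,
scanning FCS along a repeatedly scanned line, population statistics of the
pooled transit times, molecular brightness, and liquid-ordered
partitioning of probes in phase-separated vesicles. This note records the
models, the defaults and why they were chosen, and the numerical decisions
a maintainer would want to know.

## Monte Carlo simulation of hindered diffusion

Particles perform 2D Brownian motion with microscopic diffusion
coefficient `d_in`; each time step `dt` every mobile particle receives
independent per-axis Gaussian displacements with standard deviation
`sqrt(2 * d_in * dt)`. Three modes:

* **free** — unrestricted motion.
* **trapped** — a two-state Markov model of transient molecular complex
  formation. Before each displacement, a mobile particle becomes immobile
  with probability `p_trap` per step and an immobile one is released with
  probability `p_untrap` (a newly released particle moves in the same
  step). The stationary trapped fraction is `p_trap/(p_trap+p_untrap)` and
  the long-time diffusion coefficient is `d_in` times the mobile fraction.
  Trapped particles remain fluorescent: immobilized, still-emitting
  molecules are what produces the characteristic slow component in the
  correlation function.
* **hop** — meshwork-compartmentalized diffusion. The domain is tiled by a
  Voronoi partition whose seed points follow a uniform Poisson process of
  density `1/mesh_size^2`, so `sqrt(mean cell area)` equals the requested
  characteristic mesh size up to sampling error. A proposed step that
  would cross a cell boundary is accepted with probability `p_hop`;
  otherwise the particle "bounces", implemented as move rejection (the
  particle keeps its position for that step). Rejection is the standard
  lattice-free approximation to a reflecting barrier: it is unambiguous at
  arbitrarily shaped Voronoi edges and preserves detailed balance within a
  cell.

Defaults are the reference study conditions: 350 particles, `d_in` =
1 um^2/s, `dt` = 1 us, 20 s duration, 3 um domain, 250 nm spot, `p_trap` =
`p_untrap` = 5e-5 per step, 110 nm mesh, `p_hop` = 0.05.

**Domain geometry.** The default domain is a periodic square (torus) of
side 3 um. A "circle wrapped at the edges" is geometrically ambiguous;
the torus preserves uniform density and the stated length scale. An
optional circular domain with antipodal re-entry (`domain_shape='circle'`)
is provided for comparison.

**Detection.** The observation spot is a Gaussian placed at the domain
center: the apparent intensity is `sum_i exp(-2 r_i^2 / w0^2)` with `r_i`
the minimal-image distance to the spot center. The configured 250 nm spot
size is interpreted as the full width at half maximum by default and
converted to the 1/e^2 radius `w0 = FWHM / sqrt(2 ln 2)` (~212 nm); the
convention is a tagged field because instrument papers quote either.
Detection is noiseless by default ("apparent intensity"); Poisson photon
sampling at a configurable per-molecule count rate is available.

**Numerics.** The inner loop is a numba kernel processing chunks of
pre-drawn random numbers; a plain-numpy single-step implementation of the
same update rules is kept as the reference, and the test suite asserts the
two produce bit-identical trajectories from the same streams. Separate
seeded streams (initial positions / displacements / trap-hop state /
photon noise / mesh) make degenerate limits exact: `p_trap = 0` at a given
seed reproduces the free trajectory bit for bit. Voronoi cell membership
is evaluated by nearest-seed lookup (periodic on the torus) rasterized at
`mesh/64` (~1.7 nm for the default mesh) — comparable to the 1.4 nm rms
step, far below the 110 nm compartments, and O(1) per step.

## Correlation analysis

The multi-tau correlator evaluates

    G(tau) = <I_left I_right> / (<I_left> <I_right>) - 1

on a quasi-logarithmic grid: the first two octaves at the raw interval,
then 16 points per octave on traces progressively binned by factors of
two. The symmetric normalization (means over the overlapping segments)
removes leading-order drift bias and reduces to `<dI dI>/<I>^2` for
stationary signals. An O(N * n_lags) direct-summation correlator
evaluating the definition at every integer lag is the testing oracle.

Segment-averaged curves (`average_segment_curves`) give per-lag empirical
standard errors, but the per-segment mean subtraction biases G downward by
roughly `2 tau_D / T_segment` of the amplitude; segments must be hundreds
of transit times long. Pipeline fits therefore correlate full traces.

## FCS model and fitting

The fit model is the standard two-dimensional FCS law

    G(tau) = G0 [1 + T/(1-T) e^(-tau/tau_T)]
                sum_i f_i (1 + (tau/tau_D,i)^alpha)^(-1)  + G_inf

with amplitude `G0 = 1/N`, transit times `tau_D,i`, fractions summing to
one, anomalous exponent `alpha` (fixed to 1 unless freed), and an optional
triplet term. The names ("2D", "triplet", "one-component") follow the
community convention of confocal FCS fitting software.

`G_inf` is an optional free baseline. Two small, real effects make the
measured long-lag correlation sit slightly below the infinite-plane model:
the simulation domain is closed (particle number is strictly conserved, so
number fluctuations anti-correlate at long times) and any finite trace
biases the normalized estimator by about `-2 int G dtau / T`. Both are
absorbed by a constant at the ~1%-of-G0 level; fits of simulated traces a
few seconds long enable it, and recovery of `d_in` improves markedly.
Fits use weights `1/sem` when a per-lag standard error is present,
multi-start initialization (amplitude/half-decay based plus perturbed
restarts, fixed seed), and flag non-convergence instead of returning
defaults. Curve-level bootstrap uncertainty refits curves from random
contiguous half-length sub-segments of the trace (10 rounds by default).

**Calibration.** With `w0 = FWHM/sqrt(2 ln 2)`, transit times convert as
`D = w0^2 / (4 tau_D)`. A 250 nm FWHM gives the quoted lateral observation
area `pi w0^2 / 2 ~ 0.07 um^2`. Note the distinct *amplitude* area: for
this detection profile `G0 = 1/(c * pi w0^2)`, i.e. the occupancy that
sets the amplitude refers to `pi w0^2`; both areas are exposed on
`SpotCalibration`. Brightness is `cpm = <I> G0 = <I>/N`, an intensive
quantity (doubling the particle density leaves it unchanged).

## Scanning-FCS pipeline

Default geometry: a 5.2 um line of 52 pixels (100 nm), scanned at 2081 Hz
for 50 s; each pixel is treated as sampled once per scan cycle at the line
frequency (intra-line dwell timing is not modelled). The canonical order
is fixed and tested: crop the first seconds (default 10 s, initial
bleaching), multiplicative local-average photobleaching correction
(default 18 s window; `I' = I * <I>/trend` with the trend an order-1
Savitzky-Golay smooth — a plain moving average in the interior, a local
line at the trace ends where a padded boxcar would lag a decaying signal;
pixel means preserved exactly, pixels whose trend reaches zero are
flagged and excluded), then
per-pixel correlation and a 2D one-component fit (no anomalous exponent,
no triplet), pooling transit times and cpm. More than half the pixels
failing is a carpet-level error. The bleach-correction contract
(stationary mean, mean preservation) is the specification of the step;
the exact smoothing of any particular acquisition software is not
reproduced.

## Transit-time statistics

Pooled transit times are modelled as log-normal (free diffusion) or a
two-component log-normal mixture (hindered diffusion); `e^mu` is a
component's median transit time. In the mixture the slow component C1
carries weight `1-B` and the fast component C2 weight `B`. The single
model has a closed-form MLE; the mixture is maximized by
expectation-maximization with multi-start (median split of `ln t`, two
perturbed restarts, and a near-degenerate start at the single fit, which
guarantees the mixture log-likelihood dominates the nested single model).
A log-scale sigma floor of 1e-3 prevents degenerate spikes and is flagged
when active. Model choice is by BIC = k ln n - 2 ln L (k = 2 or 5; both
likelihoods are densities in t, including the `1/t` Jacobian) with plain
lower-BIC selection and the margin reported. Raw-sample MLE is primary;
the cumulative / linear / logarithmic histogram fits are retained as
diagnostics because fitting binned data is statistically inferior.

## %Lo partitioning

For a line crossing the equator of a phase-separated vesicle with one
phase on each side, the two membrane crossings are located as profile
peaks; the crossing with the higher disordered-marker reference signal is
labelled Ld. Peak intensity is the mean over a small window (default
+-1 px) around the maximum after subtracting the median of the
off-membrane profile (toggleable to raw or integrated values; the window
can be widened to the rim width for noisy images). Then

    %Lo = 100 * I_Lo / (I_Lo + I_Ld),

with ordered-phase preference when %Lo > 50. The statistic is bounded in
[0, 100], complement-symmetric, scale-invariant, and strictly increasing
in I_Lo.

## Synthetic data and what passing tests show

Generators with ground-truth sidecars produce (i) log-normal transit-time
samples, (ii) two-phase vesicle images (a blurred ring with two angular
halves, Ld-marker second channel, additive Gaussian noise; the phase
boundary sits at the poles so an equatorial line crosses each phase at its
angular center), and (iii) scanning-FCS carpets from a single simulation
run, with an optional multiplicative exponential bleaching overlay applied
at the detection stage so the bleach correction can be tested in isolation
from the diffusion physics. All generators are bit-deterministic under a
seed.

The generators emulate idealized instruments: no detector afterpulsing or
dead time, no intra-line scan timing, shot noise optional and off by
default, vesicles are perfect circles. Passing tests therefore demonstrate
correctness of the algorithms and recovery of known ground truth under
these conditions, not robustness to every artifact of real confocal data.

## Problem sizes

Analysis-grade runs in the tests and the acceptance script use the
default particle count, step size, geometry and probabilities with
simulated durations of 3-5 s (point FCS) — long enough that a trace holds
several hundred spot transits, with per-condition curves averaged over
seeds before fitting, as in multi-curve acquisition practice — and one
canonical 40 s carpet at `dt` = 10 us (the 4.5 nm rms step is still tiny
against the 212 nm waist). Statistical studies use n = 10^4 samples and
100 seeded repetitions for the BIC selection study.

## Known limitations

* Two-state trapping with exponential dwell times at these rates produces
  correlation decays whose anomalous-fit exponent hovers near 1 from
  below; strongly subdiffusive exponents require broad (non-exponential)
  immobilization-time distributions or finer meshes than the default.
* Short traces carry an O(tau_D/T) estimator bias; the `G_inf` baseline
  absorbs most of it but per-run fitted parameters at a few seconds of
  trace remain noticeably seed-dependent.
* The mixture EM can merge components whose medians are closer than about
  one log-sigma; BIC then correctly prefers the single model, so weakly
  separated populations are reported as one.
* No 3D diffusion, no photophysics inside the simulator (bleaching is a
  detection-stage overlay), no leaflet-resolved kinetics.
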