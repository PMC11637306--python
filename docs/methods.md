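# Methods

`axonwave` models how action-potential (AP) shape behaves along thin,
varicose (bouton-bearing) axons such as hippocampal mossy fibers, and
implements the measurement pipelines used to study that question:
compartmental AP simulation, seal-test capacitance measurement,
pipette/amplifier forward modelling with conductance-fit correction, and
voltage-sensitive-dye (VSD) signal processing.  Everything runs on seeded
synthetic data generated by the package itself.

## Compartmental model

The axon is a tree of 3-D points with per-point radius (SWC interchange),
cut into iso-potential compartments of at most 1 um (`morphology.discretize`).
Tapering segments are frusta: membrane area uses the slant lateral surface
(exactly additive under subdivision, so total area is invariant under
re-discretization), and the axial resistance of a frustum is
4·Ra·L/(pi·d1·d2), split into two half-resistances.

Each compartment carries:

* leak: g_L = 1/R_m, R_m = 50 kOhm·cm2, E_leak = -80 mV; C_m = 1 uF/cm2;
  Ra = 150 Ohm·cm;
* Na+: g_Na·m3h·(V - 70 mV), g_Na = 290 mS/cm2;
* backbone K+ (Kv3-like): g_K·n4·(V + 90 mV), g_K = 17 mS/cm2, with an
  optional slow cumulative inactivation gate for train protocols (below);
* compensatory K+ (Kv1-like, dendrotoxin-sensitive): a single Boltzmann
  activation gate (V1/2 = -30 mV, slope 8 mV, tau 0.2-1.2 ms) with a
  per-compartment density, zero by default;
* Ca2+: a Goldman-Hodgkin-Katz current carried by a P/Q : N : R mixture
  (6.5 : 2.5 : 1 by permeability, total 2e-4 cm/s), each subtype one
  power-2 Boltzmann activation gate (V1/2 = -5 / -12 / -20 mV) whose rates
  are Q10 = 2.5-scaled from 24 degC to the working 35 degC.  Intracellular
  Ca2+ is constant (0.1 uM vs 2 mM outside): the model computes influx,
  not Ca2+ dynamics.

Na/K gating uses the canonical squid-axon rate equations with a voltage
shift and an overall rate scale per gate species.  The defaults —
shift +5 mV (m, n), 0 mV (h); rate scales 4 (m), 14 (h), 4 (n) — were
calibrated once on the default synthetic axon so that the propagating AP
peaks near +25…+50 mV and repolarizes within ~1 ms at 35 degC, and
propagates reliably on a 0.3 um shaft.  Sodium inactivation needs its own,
faster scale: with m and h sped up together the AP peak stays pinned near
E_Na at these densities.  All rate parameters are exposed
(`ActiveDensities`) and are exactly the parameters the conductance-fitting
pipeline varies.

### Numerics

Backward Euler on the voltage with staggered exact-exponential
(Rush-Larsen) gate updates at the frozen start-of-step voltage;
the branched axial system is solved exactly each step by one child-to-root
elimination and back-substitution over compartments in parent-before-child
order.  Default dt = 4 us (250 kHz).  The GHK Ca2+ current — orders of
magnitude smaller than the Na/K currents — enters explicitly at the
start-of-step voltage; the dt/dx-halving convergence test bounds the total
discretization error below 1% RMS of the AP amplitude.  A run is flagged
unstable if any |V| exceeds 150 mV.  Voltage clamp is an ideal source in
series with the access resistance (1 kOhm when "ideal") at the clamp
compartment; the reported trace is the pipette current.  Stimulus sites are
addressed by path distance from the root, so results do not depend on the
discretization.

### Slow K+ inactivation (train protocols)

AP broadening across trains is reproduced by an optional availability gate
on the backbone K+ current with fast entry while depolarized
(tau 15 ms above -50 mV) and slow recovery at rest (tau 300 ms), floor 0.2.
A single shared time constant of hundreds of milliseconds accumulates
almost no inactivation at 40 Hz (the depolarized duty cycle is ~4%), so the
two-time-constant form — the standard description of cumulative
inactivation — is used.  The gate is off by default.

## Synthetic varicose axon

`synth.make_axon` draws an unbranched axon: 600 um of 0.3 um shaft carrying
18 boutons (4 giant) with log-normal small-bouton diameters (median 1 um)
and giant boutons of 2.5-4.5 um, at >= 15 um spacing, diameters clipped to
the 0.1-5 um range of real mossy fibers.  Bouton profiles are Gaussian
bumps whose width tracks the bouton diameter.  The first and last 150 um
are bouton-free run-in regions: the AP is triggered at one end (as the real
experiment triggers at the distant soma) and the stimulation transient
measurably distorts AP shape for ~100 um, so all shape statistics use the
central 300 um.  Every generator is a pure function of its seed.

What the generator does not emulate: branch points, filopodia, continuous
shaft-caliber drift, myelin, and the somatodendritic tree.  Passing tests
therefore demonstrate the biophysics of an isolated varicose cable, not of
a full granule-cell arbor.

## AP metrics

Onset = first pre-peak crossing of dV/dt above 100 mV/ms (sub-sample
interpolated).  AP area integrates (V - V_onset) from onset to the first
post-peak return to the onset voltage; the repolarization-only area
integrates from the peak (it avoids rise-phase contamination and is the
statistic used for size-dependence).  Duration is the width at -20 mV for
propagating simulated APs and the width at half the onset-to-peak amplitude
otherwise.  All crossing times are linearly interpolated between samples,
which is what makes the metrics stable to halving the sampling rate (the
suite asserts 2%).

## Ca2+ influx and release

Inward Ca2+ current is trapezoid-integrated over the AP; per-bouton influx
is expressed as charge density (fC/um2) so boutons of different size are
compared per unit membrane, and relative release is influx_density^2.5,
mean-normalized.  The headline spread statistic is the relative range
(max - min)/mean across boutons; the coefficient of variation
(population sd / mean) is reported alongside.

## Size dependence and compensation

With homogeneous densities on the seeded axon the per-compartment
repolarization area varies (sd ~3.8 mV·ms on ~40 mV·ms) and regresses on
local capacitance with a negative slope (~-9 mV·ms/pF, r ~ -0.05 at seed
1); across boutons the relative release range is ~56%.  The correlation is
weak — most of the variance comes from caliber-mismatch ("capacitive
sink") interactions with neighbouring regions rather than from local size
itself, which matches the weak bouton-level correlation the underlying
experimental literature reports (R2 ~ 0.25).

The compensation experiment distributes a Kv1-like density proportional to
1/local-capacitance, with the single scale chosen by a golden-section
search (log-spaced, 9 iterations over 0.25-24 mS/cm2) minimizing the
across-bouton sd of repolarization area; scales that block propagation are
rejected inside the search.  A one-parameter profile can only remove the
variance component aligned with the 1/C response direction, so the
achievable sd reduction is 1/sqrt(1 - rho2) with rho the area-vs-response
correlation; at the weak baseline correlation this is ~1.15x, and the
release range is not improved at the sd-optimal scale.  The in-silico
dendrotoxin experiment (zeroing the compensatory density of the compensated
model) reinstates the negative slope exactly and widens small-capacitance
compartments more than large ones, because they carried more of the
compensatory density.

## Seal-test capacitance measurement

Synthetic probe data come from the exact eigen-solution of a two-node
circuit (local structure through an access resistance, remote arbor behind
a large axial resistance; defaults 5 pF / 100 MOhm / 800 MOhm / 60 pF,
2% Gaussian current noise).  Transients are fitted with 1-3 exponentials by
multi-start least squares (5 log-spaced tau starts plus a start derived
from the next-lower model, which guarantees the nested-model SSE ordering);
time constants are bounded below at three samples.  The fit window is
anchored at the transient peak and spans 60 ms by default: a window
starting milliseconds after the peak loses the sub-millisecond fast
component entirely, and a short window cannot distinguish the slow arbor
component from the fit offset (both choices are configurable).

The structure capacitance is the fast-component charge C = |A0·tau_f|/dV
with A0 back-extrapolated to the step onset, corrected by the squared
voltage-division ratio (A0_fast/I0)^-2, where I0 — the total step current
at onset — is available from the fit itself.  The correction is exact for
the two-compartment circuit and reduces to the plain fast-charge formula
for an ideal clamp; without it the estimate is biased low by ~(1 - x)^2
where x is the fraction of conductance not through the pipette (~19% at
the default coupling).  Model selection prefers the bi-exponential unless
the tri-exponential improves SSE by >10% or the mono-exponential comes
within 10% of it.

## Instrument model and correction

The pipette is a 5-segment RC ladder (40 MOhm / 6 pF by default,
resistance split 60/20/10/6/4% from the tip), an access resistance
(120 MOhm), and a 12 GOhm seal leak at the tip.  Capacitance
neutralization scales the effective pipette capacitance by
(1 - fraction), default 0.9; bridge balance subtracts I·R_bridge from the
read voltage.  Recording a simulated AP through the default instrument
attenuates the amplitude and roughly doubles the half-width while changing
the AP area by only a few percent — the area's robustness to instrumental
filtering holds across a 3x3 grid of pipette settings (R in {20,40,80}
MOhm x C in {3,6,12} pF).

Correction mirrors the experimental pipeline: passive parameters
(C_m, Ra, access) are fitted to subthreshold responses with R_m fixed at
50 kOhm·cm2 (Nelder-Mead), then the Na/K parameters (two densities, two
voltage shifts, two rate scales; densities bounded at 5x default, shifts
at +/-20 mV, scales at 0.2-5x) are fitted to recorded APs from several
random initializations, and the per-start parameters are averaged.  The
native AP is predicted by rerunning the averaged parameters without the
instrument.  Experiments stimulate 100 um upstream of the pipette so the
recorded AP propagates naturally into the recording site; through-pipette
stimulation is also supported, with blanking of the brief bridge/
neutralization artifacts at pulse edges.  At desk scale (4 initializations,
150 simplex evaluations, one target AP, dt = 8 us on a 400 um axon) the
fitted densities recover ground truth within ~2% and the corrected
half-width lands within ~2% of the native one (raw recorded: ~2x off).

## VSD pipeline

The renderer produces 10 kHz stacks (64 x 46 px, 0.79 um/px) with
F = F0·bleach(t)·(1 + s·(V - V_rest)/100 mV), s = 8% per 100 mV, double
exponential bleaching (taus 50/500 ms), shot noise (Gaussian with variance
proportional to F) plus read noise, paired 250 kHz electrical references,
and per-trial AP phase jittered uniformly within one frame period plus a
4 us Gaussian detection error on the reference peak.

Processing: per-pixel bleach correction (pixels clustered into 8
mean-intensity octile bins, one double exponential per bin fitted with AP
windows excluded, mono-exponential fallback flagged); dF/F0 activity maps
around AP peaks (+/-0.2 ms vs pre-event baseline); averaging over <=5 um
path segments; spike-locked shift-and-mean oversampling (pool aligned
samples over trials, sort, block-average by 8); two-step zero-phase
Butterworth filtering (cutoffs at/above Nyquist skipped and reported); and
the peak-normalized AP area over a 0.6 ms window starting 0.05 or 0.1 ms
after the peak (normalization because VSD amplitudes depend on background
intensity).  The effective oversampled rate is defined as output blocks per
alignment-window length with a half-open window, which puts 20-22 pooled
trials at 25.0-27.4 kHz.

One 50-um field of view yields only ~10 segments, far too few to resolve
the weak area-vs-caliber correlation on the imaging side; the
`vsd_uniformity` experiment reports the correlations with that caveat
rather than asserting their sign.

## Problem sizes

Default analyses use a 600-um axon (~600 compartments), 18 ms of simulated
time per AP at 250 kHz, 9 golden-section iterations for the compensation
scale, 100 noisy probe replicates, 4x150 simplex evaluations for the
conductance fit, and 20 VSD trials of 12 ms — sizes chosen so each
experiment completes in seconds to a few minutes on one core while keeping
every estimate's sampling error well inside the tolerances the tests
assert.

## Known limitations

* The compensation experiment's one-parameter 1/C profile cannot null
  mismatch-driven AP-shape variance (see above); the package reports the
  achieved factors honestly.
* Ca2+ subtype kinetics are generic Boltzmann gates, not fits to recorded
  subtype currents; only the mixture's deactivation-on-repolarization
  behaviour matters for the influx analyses.
* The instrument model is a lumped ladder; real pipettes have
  submersion-depth-dependent distributed capacitance.
* No Ca2+ buffering, stochastic gating, myelin, branching, or network
  interactions.
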