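# Methods

This note documents the models behind `fscvsim`, the defaults they ship
with, the numerical choices, and what the simulations can and cannot say
about real preparations.

## The virtual subject

### Release–reuptake–transfer kinetics

Stimulation-evoked extracellular dopamine is modeled with two compartments.
Release enters an "unmeasured" tissue compartment C_u at rate
`DA_p(A, PW) · f` (µM/s) while the train is on; clearance is Michaelis–Menten
(the dopamine transporter, maximal rate `vmax`, half-saturation `km`); the
electrode senses a second compartment C_m coupled by first-order transfer
`k_transfer` — the standard "restricted diffusion" description of the tissue
sheath that delays and smooths the measured transient:

    dC_u/dt = DA_p(A, PW) · f · s(t) − vmax · C_u / (km + C_u)
    dC_m/dt = k_transfer · (C_u − C_m)

The discrete pulse train is rate-averaged: release is treated as a constant
inflow `DA_p · f` during the train rather than as per-pulse impulses.  At the
frequencies of interest (≥ 60 Hz) the inter-pulse interval is far below every
kinetic time constant, so the approximation is invisible in C_m.

### Recruitment

The per-pulse release increment saturates in per-phase charge q = A·PW —
axon recruitment around the stimulating electrode is approximately logistic
in charge:

    DA_p(q) = DA_max · (σ(q) − σ(0)) / (1 − σ(0)),    σ(q) = 1/(1 + e^{−(q−q50)/β})

The shift/rescale by σ(0) makes DA_p(0) exactly zero (a raw logistic would
release dopamine at zero charge) while preserving monotonicity, the
half-maximal charge q50, and the saturation level DA_max.  Because A and PW
enter only through their product, the stimulus space is effectively
one-dimensional in charge; this degeneracy matters for inverse control (see
below).

### Defaults (the simulated preparation)

These are simulation fixtures chosen to put evoked responses on the scale of
a healthy rodent striatal preparation; they are not measurements.

| parameter | default | units | note |
| --- | --- | --- | --- |
| `da_per_pulse_max` | 0.15 | µM/pulse | saturated 60 Hz, 0.5 s train peaks near 1.8 µM |
| `q50` | 1.0e−7 | C | mid-grid for 100–500 µA × 0.1–1 ms |
| `recruit_slope` | 5.0e−8 | C | sigmoid spans the device-accessible charge range |
| `vmax` | 4.0 | µM/s | striatal uptake scale |
| `km` | 0.2 | µM | transporter half-saturation |
| `k_transfer` | 2.0 | 1/s | sub-second measured-transient lag |
| `k_ads`, `k_des` | 0.2, 2.0 | 1/(µM·s), 1/s | Langmuir surface, near-linear below ~2 µM |
| `gamma_max` | 1.0 | – | coverage normalization |
| electrode `gain` | 800 | nA per unit coverage | effective low-coverage slope 80 nA/µM; maximal evoked oxidation currents land in the tens of nA |
| noise `white_sd` | 0.5 | nA/sample | ~2 % of a typical evoked peak after filtering |

Stimulator envelope: current mode 10 µA–10 mA in 10 µA steps, voltage mode
50 mV–10 V in 10 mV steps, pulse width 50 µs–2 ms, waveform slew limit
1200 V/s.  Biphasic pulses are charge-balanced with zero interphase gap.

### Integration

Fixed-step RK4, default dt = 0.5 ms (1 ms on fitting grids).  The system is
non-stiff; step-halving changes evoked peaks by < 0.1 %.  Release is
piecewise constant per step and train edges are grid-aligned in all shipped
protocols, so the integrator keeps its design order at the switching
instants.  Michaelis–Menten uptake is clamped to zero for transiently
negative stage values so RK4 excursions cannot inject mass; outputs are
floored at zero.  The inner loop is JIT-compiled with numba when available;
the numpy fallback produces identical trajectories.

### Measurement synthesis

Surface coverage follows the Langmuir ODE driven by C_m, integrated with the
exact exponential update per step (so constant inputs sit at equilibrium to
machine precision).  Each scan's current is

    static capacitive background (sign of dV/dt, mild potential dependence)
  + gain · Γ · [Gaussian ox peaks on the anodic sweep − 0.7 × Gaussian red peaks on the cathodic sweep]
  + white noise + linear drift + slow pH sinusoid + artifact spikes

Drift is referenced to the oxidation potential and scaled elsewhere by the
normalized background template; drift and pH are off by default.  Artifact
spikes are single-sample rectangles at the sample where a pulse onset lands —
deliberately the simplest model that exercises the synchronization logic;
whether the measured current tracks adsorbed (Γ) or free (C_m) dopamine is a
switch (`adsorption=None` bypasses the surface), adsorption on by default.

## Synchronization

The scan clock and stimulator share a timebase, so a per-train onset delay
(0.1 ms search grid, finer than any pulse width in range) steers every pulse
onset relative to the scan.  `compute_sync_delay` minimizes, by exhaustive
grid search over one repetition period, the number of pulse onsets landing
inside a scan at a potential within caller-supplied avoid windows (±0.15 V
around the analyte redox potentials in the demos); ties break to the
smallest delay.  Artifact position is judged at pulse onset only — pulse
widths (≤ 2 ms) are comparable to the window dwell time, so an onset-based
contract is the simplest testable one.  The "unsynchronized" condition in
the artifact demo is the worst-case phase over the same grid, since a
free-running stimulator's phase is arbitrary.

## Processing chain

Background subtraction removes the mean scan over a pre-stimulus window.
The 1 kHz third-order Butterworth filter is applied forward–backward
(zero-phase) within each scan along the 100 kS/s sample axis, with
reflective padding of 3× the filter order.  A consequence worth knowing: the
voltammetric peaks are ~0.3 ms wide in the time domain, so the filter shaves
~8 % off their amplitude.  Calibration and in-vivo readout share the chain,
so concentration estimates are unbiased; absolute current comparisons
against unfiltered data are not.  Scanwise de-trending fits a per-potential
polynomial across scans (degree 1 by default) on a caller-chosen fit window.
Time-series extraction uses nearest-sample potential lookup with no
interpolation, keeping values bit-reproducible.

## Calibration

Flow injection is modeled as a rectangular bolus smoothed by first-order
mixing (τ = 0.3 s); the flow rate is metadata only.  The per-bolus summary
is the median oxidation current over the plateau window (5τ into the bolus
to its end) — robust to edge transients.  Ordinary least squares of plateau
current on concentration gives the conversion line; the surface model is
bypassed for calibration (dilute regime, coverage ∝ concentration).

## Kinetic fitting

All responses of a characterization protocol are fit jointly — one parameter
vector, residuals concatenated — because the recruitment sigmoid is only
identifiable across responses spanning several charges.  The optimizer is
bounded trust-region least squares in log10 parameter space; multistart uses
one data-driven initialization (DA_max from the largest peak, q50 from the
half-maximal charge of the measured peak-vs-charge curve) plus Latin-
hypercube draws over the log-bounds (16 starts by default).  `km` can be
pinned via the `fixed` argument when the data cannot constrain it; default
free with bounds [0.05, 1] µM.  R² is 1 − SS_res/SS_tot over the
concatenated responses.  The protocol pairs washouts to train durations
(30 s after 0.5 s trains, 300 s after 2.0 s); responses are simulated
independently from baseline, and a closed-form Michaelis–Menten decay bound
(plus three transfer time constants) flags any cell whose washout would not
have restored baseline, as a warning rather than an error.

## Inverse controller

Architecture: 2 inputs → 7–9 tanh hidden units → 2 linear outputs, inputs
and outputs affinely normalized to ≈[−1, 1] over the training data, initial
weights uniform in [−0.5, 0.5] scaled by fan-in.  The response descriptor
pair is (peak ΔC, area over the stimulation window + 1 s); both are computed
identically from training responses and closed-loop measurements.

Because the subject depends on (A, PW) only through charge, a factorial
training grid makes the inverse one-to-many and biases an MSE-trained
network toward charge overshoot.  The shipped characterization for control
is therefore a 16-point log-spaced charge staircase (A and PW co-increasing),
which makes descriptor → (A, PW) single-valued along the operating path.
Training is batch gradient descent (default 10⁵ epochs, rate 0.2), restarted
from three seeded initializations with the lowest final *training* MSE kept —
gradient descent on this small network occasionally settles in a visibly
poorer local minimum, and selection by training loss mirrors the usual
per-dataset model selection.

Online adaptation treats each stimulation event's realized (measured
descriptor, applied raw parameters) pair as a fresh sample of the inverse
map.  `adapt_online` takes one gradient step by default; `run_closed_loop`
uses 40 backtracking steps per event (a step is kept only if the batch MSE
does not increase, the step size halving on rejection and regrowing on
acceptance — aggressive after a disturbance, incapable of diverging) over a
sliding window of the last 18 examples.  One further piece of bookkeeping
proved essential: the target descriptor is built from a peak→area ratio, and
that ratio is re-estimated from the measured descriptor window each event.
After a sensitivity change the training-time ratio would place target
queries off the manifold the network is being adapted on, which — not the
weight updates — was the dominant tracking-error source in development.

Targets above the largest training peak are flagged unreachable and the loop
continues.  Predicted parameters are clamped to the stimulator envelope and
snapped to the 10 µA grid before application; adaptation examples use the
raw (unsnapped) outputs so a zero-error event leaves the weights unchanged.

## Problem sizes in the shipped tests

Characterizations use 0.5 s trains at 60 Hz with 0.5 s pre- and 2 s
post-stimulus windows (3 s per response, 1 ms fitting grid); closed-loop
sessions run 18 events; the parameter-recovery suite fits 8-response
protocols for 50 random subjects with 4 multistarts.  These sizes keep the
whole suite in the low minutes on one core while leaving every estimate far
from its identifiability floor.

## What the generator does and does not emulate

Captured: saturating dose–response in amplitude and pulse width, restricted-
diffusion lag, adsorption-shaped measurement, capacitive background, white
noise, linear drift, pH-like slow oscillation, stimulation artifacts, up to
four channels with independent parameters, sensitivity drift between
calibration and experiment.

Not captured: diffusion-limited cyclic voltammetry theory (peak shapes are
Gaussian stand-ins, not Butler–Volmer solutions), electrode fouling
chemistry, multi-analyte mixtures and their unmixing, tissue heterogeneity
and electrode placement effects, hemodynamic/physiological confounds, and
any hardware artifact beyond a single-sample spike.  Passing tests therefore
demonstrate that the algorithms are correct and the loop is stable under
realistic scales and noise — not that the specific kinetic constants
generalize to any particular animal.

## Known limitations

- The kinetic fit assumes all responses share a time grid and a baseline of
  zero after background subtraction.
- Parameter recovery is demonstrated for data generated by the same model
  family; structural mismatch (e.g. true per-pulse impulsive release) is not
  explored.
- The controller descriptor pair is effectively one-dimensional for this
  subject; controlling genuinely two-dimensional response features (e.g.
  peak and duration independently) would need a subject whose response
  breaks the charge degeneracy.
- Voltage-regulated stimulation carries no load model, so charge per pulse
  is undefined in that mode by design.
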