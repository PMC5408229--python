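# fscvsim

A software sandbox for closed-loop neurochemical sensing and stimulation
control.  `fscvsim` replaces the in-vivo half of a deep-brain-stimulation
(DBS) + fast-scan cyclic voltammetry (FSCV) experiment with a virtual
dopaminergic subject, so that every stage of the loop — waveform generation,
stimulus–scan synchronization, recording synthesis, signal processing,
electrode calibration, kinetic-model fitting, and adaptive neural-network
control of evoked dopamine — can be developed and tested on a desk, with no
hardware and no animal.

It is aimed at researchers building closed-loop neuromodulation pipelines
(control engineers who need a subject to iterate against, electrochemists
prototyping processing chains, and methods developers who want end-to-end
regression tests for an FSCV control stack).

## The models at the core

**Evoked dopamine kinetics.**  Stimulation with amplitude *A* and per-phase
pulse width *PW* at frequency *f* drives release into a tissue compartment
C<sub>u</sub>, cleared by Michaelis–Menten uptake and sensed through a
restricted-diffusion compartment C<sub>m</sub>:

    dC_u/dt = DA_p(A, PW) · f · s(t) − V_max · C_u / (K_m + C_u)
    dC_m/dt = k_T · (C_u − C_m)

where s(t) indicates the stimulus train and the per-pulse release increment
DA_p is logistic in per-phase charge q = A·PW (half-maximal at q₅₀, scale β),
rescaled so DA_p(0) = 0.  Integration is fixed-step RK4.

**Measurement.**  Dopamine adsorbs to the carbon-fiber surface with Langmuir
kinetics, dΓ/dt = k_ads·C_m·(Γ_max − Γ) − k_des·Γ; each 400 V/s triangular
scan (−0.4 → +1.45 → −0.4 V at 10 Hz) is rendered as a capacitive background
plus Gaussian oxidation (+0.6 V) and reduction (−0.2 V) peaks with amplitude
gain·Γ, plus white noise, drift, and single-sample stimulation-artifact
spikes.  Processing is the standard FSCV chain: background subtraction,
1 kHz third-order zero-phase Butterworth filtering, de-trending, and
nearest-sample extraction of time series and cyclic voltammograms.

**Control.**  A 2-input / 2-output network with 7–9 tanh hidden units learns
the *inverse* map from a desired response descriptor (peak ΔC, response
area) to the (amplitude, pulse width) that evokes it, trained by batch
gradient descent on MSE and adapted online, a few backtracking gradient
steps per stimulation event, so the loop tracks electrode drift and other
slow changes.

## Worked example

Calibrate a virtual electrode by flow-injection analysis (5-s boluses of
0.1/0.5/1.0 µM dopamine past the sensor), then run a full closed-loop
session — characterization, inverse-network training, then six target peaks
spanning 15–60 % of the maximal evoked response, three repetitions each:

```
$ fscvsim calibrate
{
  "slope_nA_per_uM": 9.166340997555523,
  "intercept_nA": -1.3322676295501878e-14,
  "r_squared": 1.0,
  ...
}

$ fscvsim control --seed 1 --out session.json --log session.tsv
{
  "n_events": 18,
  "final_mse": 0.000684973781563758,
  "regression_slope": 1.0425020914541698,
  "regression_intercept": -0.017603891591978393,
  "regression_r2": 0.9793823108904662,
  "pooled_r2": 0.9777508593328438
}
```

The calibration slope (≈9.17 nA/µM for a 10 nA/µM electrode) reflects the
~8 % attenuation of the sharp voltammetric peak by the 1 kHz zero-phase
filter — the same chain is applied in vivo, so concentration estimates stay
unbiased.  In the session summary, `regression_r2` is the squared Pearson
correlation between target and evoked peak dopamine across the 18 events
(slope ≈ 1: the controller evokes what it is asked for), and `pooled_r2`
scores the evoked peaks against the targets themselves, so any systematic
transient would pull it down.  `session.tsv` holds the per-event log
(target, predicted amplitude and pulse width, evoked peak, error).

Stimulus–scan synchronization, the other headline feature, is demonstrated
by:

```
$ fscvsim demo artifact
...
{ "frequency_hz": 130.0, "n_pulses": 261,
  "unsynchronized_in_window": 41, "sync_delay_ms": 0.0,
  "synchronized_in_window": 0 }
```

i.e. a free-running 130 Hz stimulator can drop 41 artifact spikes onto the
dopamine redox potentials in a 2-s train; the computed onset delay drops
that to zero.

## Layout

| module | contents |
| --- | --- |
| `fscvsim.waveforms` | potential programs, sampling, sync-delay search |
| `fscvsim.stimulus` | stimulator envelope, validation, charge, pulse timing |
| `fscvsim.subject` | compartment kinetics, surface model, recording synthesis |
| `fscvsim.processing` | background subtraction, filtering, extraction, redox peaks |
| `fscvsim.calibration` | flow-injection simulation, linear calibration |
| `fscvsim.kinetics` | characterization protocol, joint model fitting |
| `fscvsim.controller` | ANN inverse controller, online adaptation, closed loop |
| `fscvsim.pipeline` / `fscvsim.cli` | demos, config plumbing, `fscvsim` CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
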