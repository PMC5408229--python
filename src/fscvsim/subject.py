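"""Virtual dopaminergic subject: evoked-release kinetics and FSCV synthesis.

This module stands in for the anesthetized animal plus implanted carbon-fiber
microelectrode.  It has two halves:

1. A compartmental model of stimulation-evoked extracellular dopamine.
   Release into an "unmeasured" tissue compartment C_u is driven at
   ``DA_p(A, PW) * f`` uM/s during the stimulus train, where the per-pulse
   increment DA_p follows a saturating sigmoid in per-phase charge
   q = A * PW (recruitment of fibers around the stimulating electrode is
   approximately logistic in charge).  Clearance is Michaelis–Menten
   (dopamine transporter): ``vmax * C / (km + C)``.  The electrode senses a
   second compartment C_m coupled by first-order transfer ``k_transfer``
   (restricted diffusion through the tissue sheath around the probe):

       dC_u/dt = DA_p(A,PW) * f * s(t) - vmax * C_u / (km + C_u)
       dC_m/dt = k_transfer * (C_u - C_m)

   with s(t) = 1 during the train and 0 otherwise.  Integration is
   fixed-step RK4 (default dt = 0.5 ms): the system is not stiff, the
   integrator is deterministic, and convergence is testable by step halving.

2. An FSCV measurement synthesizer.  Dopamine adsorbs to the carbon surface
   (Langmuir kinetics, coverage Γ in [0, gamma_max]):

       dΓ/dt = k_ads * C_m * (gamma_max - Γ) - k_des * Γ

   and each scan's current is a static capacitive background template plus
   Gaussian oxidation/reduction peaks scaled by ``gain * Γ``, plus white
   noise, slow drift, optional pH sinusoid, and single-sample stimulation
   artifact spikes wherever a pulse onset falls inside a scan window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._accel import integrate_release_reuptake
from .scanio import ScanMatrix
from .stimulus import StimulusTrain, pulse_onset_times
from .waveforms import (
    FscvWaveform,
    anodic_mask,
    n_sweep_samples,
    sweep_potentials,
    triangular_dopamine_waveform,
)

__all__ = [
    "KineticParams",
    "AnalyteSignature",
    "NoiseModel",
    "SurfaceAdsorption",
    "default_rodent_params",
    "dopamine_signature",
    "serotonin_signature",
    "adenosine_signature",
    "recruitment_per_pulse",
    "simulate_compartments",
    "simulate_concentration",
    "simulate_batch",
    "dose_response_surface",
    "surface_coverage",
    "langmuir_steady_state",
    "background_template",
    "synthesize_recording",
    "VirtualSubject",
]


# ---------------------------------------------------------------------------
# parameters and signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """Release / reuptake / transfer / adsorption parameters.

    Units: concentrations in uM, times in s, charge in coulombs.

    da_per_pulse_max : maximal per-pulse release increment (uM/pulse)
    q50              : per-phase charge at half-maximal recruitment (C)
    recruit_slope    : charge scale of the recruitment sigmoid (C)
    vmax, km         : Michaelis–Menten uptake (uM/s, uM)
    k_transfer       : tissue-to-electrode transfer rate (1/s)
    k_ads, k_des     : Langmuir adsorption/desorption (1/(uM s), 1/s)
    gamma_max        : dimensionless surface capacity
    baseline         : resting extracellular concentration offset (uM)
    """

    da_per_pulse_max: float = 0.15
    q50: float = 1.0e-7
    recruit_slope: float = 5.0e-8
    vmax: float = 4.0
    km: float = 0.2
    k_transfer: float = 2.0
    k_ads: float = 0.2
    k_des: float = 2.0
    gamma_max: float = 1.0
    baseline: float = 0.0

    def __post_init__(self):
        for name in ("da_per_pulse_max", "q50", "recruit_slope", "vmax", "k_transfer", "k_ads", "k_des"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.km <= 0:
            raise ValueError("km must be positive")
        if self.gamma_max <= 0:
            raise ValueError("gamma_max must be positive")

    def adsorption(self) -> "SurfaceAdsorption":
        return SurfaceAdsorption(self.k_ads, self.k_des, self.gamma_max)


def default_rodent_params() -> KineticParams:
    """Rodent-like defaults (striatal evoked dopamine scale).  These are
    simulation fixtures, not claims about any particular animal."""
    return KineticParams()


@dataclass(frozen=True)
class SurfaceAdsorption:
    """Langmuir adsorption constants for the electrode surface."""

    k_ads: float = 0.2
    k_des: float = 2.0
    gamma_max: float = 1.0


@dataclass(frozen=True)
class AnalyteSignature:
    """Voltammetric fingerprint of one analyte.

    ``gain`` scales the oxidation-peak current per unit surface coverage
    (nA); when adsorption is bypassed the coverage equals concentration and
    the same field reads as nA/uM.  Reduction peaks are drawn at
    ``red_fraction`` of the oxidation amplitude, inverted.
    """

    name: str
    ox_potentials: tuple
    red_potentials: tuple
    peak_width: float = 0.12
    gain: float = 800.0
    red_fraction: float = 0.7

    def __post_init__(self):
        object.__setattr__(self, "ox_potentials", tuple(float(v) for v in self.ox_potentials))
        object.__setattr__(self, "red_potentials", tuple(float(v) for v in self.red_potentials))
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")


def dopamine_signature(gain: float = 800.0) -> AnalyteSignature:
    """Dopamine: oxidation ~+0.6 V, reduction ~-0.2 V (vs Ag/AgCl)."""
    return AnalyteSignature("dopamine", (0.6,), (-0.2,), 0.12, gain)


def serotonin_signature(gain: float = 800.0) -> AnalyteSignature:
    """Serotonin: oxidation ~+0.6 V, reduction ~-0.1 V (N-shaped waveform)."""
    return AnalyteSignature("serotonin", (0.6,), (-0.1,), 0.10, gain)


def adenosine_signature(gain: float = 800.0) -> AnalyteSignature:
    """Adenosine: primary oxidation ~+1.5 V with a secondary peak at +1.0 V."""
    return AnalyteSignature("adenosine", (1.5, 1.0), (), 0.12, gain)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections added on top of the deterministic scan model.

    white_sd           : per-sample white noise, nA
    drift_rate         : linear drift at the oxidation potential, nA/minute
    ph_shift_amplitude : amplitude of a slow sinusoidal pH-like shift, nA
    ph_period_s        : period of that sinusoid, s
    artifact_amplitude : single-sample stimulation artifact spike height, nA
    rng_seed           : seed of the generator owned by this model (no
                         global state; a fixed seed gives bit-identical
                         recordings)
    """

    white_sd: float = 0.5
    drift_rate: float = 0.0
    ph_shift_amplitude: float = 0.0
    ph_period_s: float = 60.0
    artifact_amplitude: float = 100.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.white_sd < 0 or self.ph_shift_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def recruitment_per_pulse(params: KineticParams, amplitude: float, pulse_width: float) -> float:
    """Per-pulse release increment DA_p(A, PW), uM.

    Logistic in per-phase charge q = A * PW, shifted and rescaled so that
    DA_p(0) = 0 exactly and DA_p -> da_per_pulse_max as q -> inf:

        DA_p(q) = da_max * (sigma(q) - sigma(0)) / (1 - sigma(0)),
        sigma(q) = 1 / (1 + exp(-(q - q50) / recruit_slope))

    The raw logistic has a small positive value at q = 0; the shift keeps
    zero-amplitude stimulation release-free while preserving monotonicity
    and the saturation level.
    """
    q = amplitude * pulse_width
    if q <= 0 or params.da_per_pulse_max == 0:
        return 0.0
    if params.recruit_slope == 0:
        return params.da_per_pulse_max if q > params.q50 else 0.0
    s0 = 1.0 / (1.0 + math.exp(min(params.q50 / params.recruit_slope, 700.0)))
    s = 1.0 / (1.0 + math.exp(np.clip(-(q - params.q50) / params.recruit_slope, -700.0, 700.0)))
    return params.da_per_pulse_max * (s - s0) / (1.0 - s0)


def _check_uniform_grid(t_grid: np.ndarray) -> float:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two points")
    dt = float(t[1] - t[0])
    if dt <= 0 or not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-12):
        raise ValueError("t_grid must be uniform and increasing")
    if dt > 1e-3 + 1e-12:
        raise ValueError("t_grid step must be <= 1 ms")
    return dt


def _release_matrix(
    params: KineticParams,
    stims: Sequence[StimulusTrain],
    t_grid: np.ndarray,
    stim_starts: Sequence[float],
) -> np.ndarray:
    """Per-step release rates (uM/s), piecewise constant on each grid step."""
    t = np.asarray(t_grid, dtype=float)
    left = t[:-1]  # step value taken at the left edge
    release = np.zeros((len(stims), left.size))
    for i, (stim, start) in enumerate(zip(stims, stim_starts)):
        da_p = recruitment_per_pulse(params, stim.amplitude, stim.pulse_width)
        if da_p == 0.0 or stim.duration <= 0:
            continue
        on = (left >= start - 1e-12) & (left < start + stim.duration - 1e-12)
        release[i, on] = da_p * stim.frequency
    return release


def simulate_batch(
    params: KineticParams,
    stims: Sequence[StimulusTrain],
    t_grid: np.ndarray,
    stim_starts: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Measured-compartment responses for several trains on a shared grid.

    Returns ``C_m`` with shape (n_stims, len(t_grid)); baseline included.
    This is the vectorized core behind both the subject and kinetic fitting.
    """
    dt = _check_uniform_grid(t_grid)
    if stim_starts is None:
        stim_starts = [0.0] * len(stims)
    release = _release_matrix(params, stims, t_grid, stim_starts)
    _, c_m = integrate_release_reuptake(release, dt, params.vmax, params.km, params.k_transfer)
    return np.maximum(c_m, 0.0) + params.baseline


def simulate_compartments(
    params: KineticParams,
    stim: StimulusTrain,
    t_grid: np.ndarray,
    stim_start: float = 0.0,
):
    """Both compartments (C_u, C_m) for one train; baseline included."""
    dt = _check_uniform_grid(t_grid)
    release = _release_matrix(params, [stim], t_grid, [stim_start])
    c_u, c_m = integrate_release_reuptake(release, dt, params.vmax, params.km, params.k_transfer)
    return (
        np.maximum(c_u[0], 0.0) + params.baseline,
        np.maximum(c_m[0], 0.0) + params.baseline,
    )


def simulate_concentration(
    params: KineticParams,
    stim: StimulusTrain,
    t_grid: np.ndarray,
    stim_start: float = 0.0,
) -> np.ndarray:
    """Measured-compartment concentration C_m(t), uM, on ``t_grid``.

    Non-negative everywhere; with zero-amplitude stimulation the output is
    identically the baseline, and after the train it relaxes back to
    baseline (Michaelis–Menten clearance plus first-order transfer).
    """
    return simulate_batch(params, [stim], t_grid, [stim_start])[0]


def dose_response_surface(
    params: KineticParams,
    amplitudes: Sequence[float],
    pulse_widths: Sequence[float],
    stim_template: StimulusTrain,
    dt: float = 5e-4,
    settle_s: float = 2.5,
) -> np.ndarray:
    """Peak evoked ΔC_m for every (amplitude, pulse width) pair.

    Returns an array of shape (len(amplitudes), len(pulse_widths)),
    nondecreasing along both axes (release is monotone in charge) and
    saturating at high charge.
    """
    amplitudes = list(amplitudes)
    pulse_widths = list(pulse_widths)
    if not amplitudes or not pulse_widths:
        raise ValueError("amplitude and pulse-width grids must be non-empty")
    stims = [
        replace(stim_template, amplitude=a, pulse_width=pw)
        for a in amplitudes
        for pw in pulse_widths
    ]
    t_end = stim_template.duration + settle_s
    t_grid = np.arange(0.0, t_end + dt / 2, dt)
    c_m = simulate_batch(params, stims, t_grid)
    peaks = c_m.max(axis=1) - params.baseline
    return peaks.reshape(len(amplitudes), len(pulse_widths))


# ---------------------------------------------------------------------------
# electrode surface and scan synthesis
# ---------------------------------------------------------------------------


def langmuir_steady_state(ads: SurfaceAdsorption, concentration: float) -> float:
    """Equilibrium coverage Γ for constant concentration."""
    denom = ads.k_ads * concentration + ads.k_des
    if denom == 0:
        return 0.0
    return ads.gamma_max * ads.k_ads * concentration / denom


def surface_coverage(
    t_grid: np.ndarray,
    conc: np.ndarray,
    ads: SurfaceAdsorption,
    gamma0: Optional[float] = None,
) -> np.ndarray:
    """Integrate dΓ/dt = k_ads C (gamma_max - Γ) - k_des Γ along ``t_grid``.

    With concentration held piecewise constant on each step the ODE is
    linear; the exact exponential update is used, so a constant input sits
    at its Langmuir equilibrium to machine precision.  ``gamma0`` defaults
    to the equilibrium coverage for the initial concentration.
    """
    t = np.asarray(t_grid, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape:
        raise ValueError("t_grid and conc must have the same shape")
    gamma = np.empty_like(c)
    gamma[0] = langmuir_steady_state(ads, c[0]) if gamma0 is None else gamma0
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        b = ads.k_ads * c[i - 1] + ads.k_des
        g_inf = ads.gamma_max * ads.k_ads * c[i - 1] / b if b > 0 else 0.0
        gamma[i] = g_inf + (gamma[i - 1] - g_inf) * math.exp(-b * dt)
    return gamma


def background_template(waveform: FscvWaveform, amplitude: float = 200.0) -> np.ndarray:
    """Static capacitive background over the sweep samples, nA.

    Capacitive current follows C_dl * dV/dt: sign set by the sweep direction,
    with a mild linear potential dependence standing in for the
    potential-dependent double-layer capacitance.  The template is identical
    for every scan, so background subtraction removes it exactly.
    """
    pots = sweep_potentials(waveform)
    mask = anodic_mask(waveform)
    sign = np.where(mask, 1.0, -1.0)
    lo, hi = pots.min(), pots.max()
    shape = 1.0 + 0.2 * (pots - lo) / (hi - lo) if hi > lo else np.ones_like(pots)
    return amplitude * sign * shape


def _analyte_unit_template(waveform: FscvWaveform, signature: AnalyteSignature) -> np.ndarray:
    """Voltammogram of the analyte at unit coverage (unit gain)."""
    pots = sweep_potentials(waveform)
    mask = anodic_mask(waveform)
    lo, hi = pots.min(), pots.max()
    for p in signature.ox_potentials + signature.red_potentials:
        if not (lo - 1e-9 <= p <= hi + 1e-9):
            raise ValueError(
                f"{signature.name} redox potential {p:+.2f} V lies outside the "
                f"waveform range [{lo:+.2f}, {hi:+.2f}] V"
            )
    w2 = 2.0 * signature.peak_width**2
    tpl = np.zeros_like(pots)
    for p in signature.ox_potentials:
        tpl += np.where(mask, np.exp(-((pots - p) ** 2) / w2), 0.0)
    for p in signature.red_potentials:
        tpl -= signature.red_fraction * np.where(~mask, np.exp(-((pots - p) ** 2) / w2), 0.0)
    return tpl


def synthesize_recording(
    t_grid: np.ndarray,
    conc: np.ndarray,
    waveform: FscvWaveform,
    signature: AnalyteSignature,
    noise: Optional[NoiseModel] = None,
    artifact_times: Sequence[float] = (),
    adsorption: Optional[SurfaceAdsorption] = None,
    background_amplitude: float = 200.0,
    channel_id: str = "ch0",
) -> ScanMatrix:
    """Render a concentration time course into an FSCV ScanMatrix.

    Parameters
    ----------
    t_grid, conc:
        Concentration series C_m(t), uM, sampled at least at the scan rate.
    adsorption:
        Langmuir constants; coverage Γ then drives the analyte peaks with
        oxidation amplitude ``gain * Γ``.  ``None`` bypasses the surface
        (coverage := concentration), e.g. for flow-injection calibration in
        the linear regime.
    artifact_times:
        Absolute pulse-onset times; each one falling inside a scan window
        adds a single-sample rectangle of ``artifact_amplitude`` nA.
    noise:
        ``None`` disables white noise, drift, and pH shift entirely.
    """
    t = np.asarray(t_grid, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("t_grid and conc must be matching 1-D arrays")
    period = waveform.period
    if t.size > 1 and (t[1] - t[0]) > period + 1e-12:
        raise ValueError("concentration series must be sampled at least at the scan rate")

    n_scans = int(np.floor((t[-1] - waveform.scan_duration) / period + 1e-9)) + 1
    if n_scans < 1:
        raise ValueError("concentration series shorter than one scan")
    scan_times = np.arange(n_scans) * period

    if adsorption is not None:
        coverage_full = surface_coverage(t, c, adsorption)
    else:
        coverage_full = c
    coverage = np.interp(scan_times, t, coverage_full)

    pots = sweep_potentials(waveform)
    n_samp = n_sweep_samples(waveform)
    bg = background_template(waveform, background_amplitude)
    tpl = _analyte_unit_template(waveform, signature)

    currents = np.tile(bg, (n_scans, 1)) + signature.gain * coverage[:, None] * tpl[None, :]

    if noise is not None:
        rng = np.random.default_rng(noise.rng_seed)
        if noise.drift_rate != 0.0 or noise.ph_shift_amplitude != 0.0:
            # drift is referenced to the primary oxidation potential and scaled
            # by the (normalized) background template at other potentials
            mask = anodic_mask(waveform)
            ox_candidates = np.where(mask)[0]
            j_ox = ox_candidates[np.argmin(np.abs(pots[ox_candidates] - signature.ox_potentials[0]))]
            norm_tpl = bg / bg[j_ox] if bg[j_ox] != 0 else np.ones_like(bg)
            if noise.drift_rate != 0.0:
                currents += noise.drift_rate * (scan_times / 60.0)[:, None] * norm_tpl[None, :]
            if noise.ph_shift_amplitude != 0.0:
                ph = noise.ph_shift_amplitude * np.sin(2 * np.pi * scan_times / noise.ph_period_s)
                currents += ph[:, None] * norm_tpl[None, :]
        if noise.white_sd > 0:
            currents += rng.normal(0.0, noise.white_sd, size=currents.shape)
        for pulse_t in artifact_times:
            k = int(np.floor(pulse_t / period + 1e-12))
            if not (0 <= k < n_scans):
                continue
            rel = pulse_t - k * period
            j = int(round(rel * waveform.sample_rate))
            if 0 <= j < n_samp and rel < waveform.scan_duration - 1e-12:
                currents[k, j] += noise.artifact_amplitude

    return ScanMatrix(currents, pots, scan_times, waveform, channel_id)


# ---------------------------------------------------------------------------
# the assembled subject
# ---------------------------------------------------------------------------


@dataclass
class VirtualSubject:
    """Kinetics + electrode + noise bundled as one stimulatable preparation.

    ``gain_scale`` multiplies the electrode sensitivity at measurement time
    and models sensitivity drift between calibration and the experiment
    (the closed-loop adaptation scenario).
    """

    params: KineticParams = field(default_factory=default_rodent_params)
    waveform: FscvWaveform = field(default_factory=triangular_dopamine_waveform)
    signature: AnalyteSignature = field(default_factory=dopamine_signature)
    noise: Optional[NoiseModel] = field(default_factory=NoiseModel)
    background_amplitude: float = 200.0
    use_adsorption: bool = True
    gain_scale: float = 1.0
    channel_id: str = "ch0"
    dt: float = 5e-4

    def respond(
        self,
        stim: StimulusTrain,
        pre_s: float = 0.5,
        post_s: float = 2.0,
        sync_delay_ms: Optional[float] = None,
        include_artifacts: bool = False,
    ):
        """Stimulate and record.

        The train starts ``pre_s`` seconds into the recording (baseline
        scans first) and the recording extends ``post_s`` seconds past the
        train.  Returns ``(t_grid, conc, scan_matrix)``.
        """
        t_end = pre_s + stim.duration + post_s
        t_grid = np.arange(0.0, t_end + self.dt / 2, self.dt)
        conc = simulate_concentration(self.params, stim, t_grid, stim_start=pre_s)
        artifacts: Sequence[float] = ()
        if include_artifacts and self.noise is not None:
            delay_ms = stim.onset_delay if sync_delay_ms is None else sync_delay_ms
            onsets = pulse_onset_times(replace(stim, onset_delay=delay_ms)) + pre_s
            artifacts = onsets
        signature = (
            replace(self.signature, gain=self.signature.gain * self.gain_scale)
            if self.gain_scale != 1.0
            else self.signature
        )
        m = synthesize_recording(
            t_grid,
            conc,
            self.waveform,
            signature,
            noise=self.noise,
            artifact_times=artifacts,
            adsorption=self.params.adsorption() if self.use_adsorption else None,
            background_amplitude=self.background_amplitude,
            channel_id=self.channel_id,
        )
        return t_grid, conc, m
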