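"""Flow-injection calibration of the carbon-fiber microelectrode.

In vitro, timed boluses of known dopamine concentration (e.g. 0.1, 0.5 and
1.0 uM, five seconds each) are carried past the electrode; the plateau
oxidation current of each bolus versus its concentration is fit by ordinary
least squares, and the resulting line converts in vivo oxidation currents
into concentration estimates.  The bolus profile is a rectangular step
smoothed by first-order mixing in the flow cell; the pump's flow rate is
metadata only (no hydrodynamic model).  The per-bolus summary statistic is
the median over plateau scans, which is robust to edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .processing import background_subtract, extract_timeseries, lowpass_scans
from .scanio import ScanMatrix
from .subject import AnalyteSignature, NoiseModel, dopamine_signature, synthesize_recording
from .waveforms import FscvWaveform, triangular_dopamine_waveform

__all__ = [
    "CalibrationCurve",
    "simulate_flow_injection",
    "bolus_plateau_current",
    "fit_calibration",
    "current_to_concentration",
    "calibrate_electrode",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear current-to-concentration calibration.

    slope in nA/uM, intercept in nA, r_squared in [0, 1].
    """

    slope: float
    intercept: float
    r_squared: float
    concentrations_used: tuple

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def _bolus_profile(t: np.ndarray, concentration: float, pre_s: float, duration: float, tau: float) -> np.ndarray:
    """First-order mixing response to a rectangular bolus."""
    c = np.zeros_like(t)
    rising = (t >= pre_s) & (t < pre_s + duration)
    c[rising] = concentration * (1.0 - np.exp(-(t[rising] - pre_s) / tau))
    after = t >= pre_s + duration
    c_end = concentration * (1.0 - np.exp(-duration / tau))
    c[after] = c_end * np.exp(-(t[after] - pre_s - duration) / tau)
    return c


def simulate_flow_injection(
    concentrations: Sequence[float],
    bolus_duration: float = 5.0,
    gain: float = 10.0,
    noise: Optional[NoiseModel] = None,
    waveform: Optional[FscvWaveform] = None,
    signature: Optional[AnalyteSignature] = None,
    mixing_tau: float = 0.3,
    pre_s: float = 2.0,
    post_s: float = 3.0,
    background_amplitude: float = 200.0,
) -> List[ScanMatrix]:
    """One recording per bolus: ``pre_s`` of buffer, the bolus, then washout.

    The electrode responds linearly (``gain`` nA/uM; the Langmuir surface is
    bypassed, as appropriate for the dilute calibration regime), so the
    noiseless plateau currents of 0.1/0.5/1.0 uM boluses sit in 1:5:10
    ratio.  Successive boluses get distinct noise seeds derived from
    ``noise.rng_seed``.
    """
    concentrations = [float(c) for c in concentrations]
    if any(c <= 0 for c in concentrations):
        raise ValueError("bolus concentrations must be positive")
    waveform = waveform or triangular_dopamine_waveform()
    signature = signature or dopamine_signature()
    signature = replace(signature, gain=gain)
    t_end = pre_s + bolus_duration + post_s
    t = np.arange(0.0, t_end, 0.01)
    out = []
    for i, c in enumerate(concentrations):
        bolus_noise = replace(noise, rng_seed=noise.rng_seed + i) if noise is not None else None
        conc = _bolus_profile(t, c, pre_s, bolus_duration, mixing_tau)
        out.append(
            synthesize_recording(
                t,
                conc,
                waveform,
                signature,
                noise=bolus_noise,
                adsorption=None,
                background_amplitude=background_amplitude,
                channel_id=f"bolus{i}",
            )
        )
    return out


def bolus_plateau_current(
    m: ScanMatrix,
    pre_s: float = 2.0,
    bolus_duration: float = 5.0,
    mixing_tau: float = 0.3,
    ox_potential: float = 0.6,
) -> float:
    """Median oxidation current (nA) over the bolus plateau scans.

    Background scans are taken before the bolus; the plateau window starts
    five mixing time constants into the bolus.
    """
    n_bg = int(np.sum(m.scan_times < pre_s - 1e-9))
    if n_bg < 1:
        raise ValueError("recording has no pre-bolus scans to use as background")
    sub = lowpass_scans(background_subtract(m, (0, n_bg)))
    times, series = extract_timeseries(sub, ox_potential, "anodic")
    plateau = (times >= pre_s + 5 * mixing_tau) & (times <= pre_s + bolus_duration)
    if not plateau.any():
        raise ValueError("bolus too short for a plateau window")
    return float(np.median(series[plateau]))


def fit_calibration(
    peak_currents: Sequence[float], concentrations: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least squares of oxidation current on concentration."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(peak_currents, dtype=float)
    if x.size != y.size:
        raise ValueError("peak_currents and concentrations must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("calibration needs >= 2 distinct concentrations")
    fit = stats.linregress(x, y)
    return CalibrationCurve(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), tuple(np.unique(x))
    )


def current_to_concentration(current, curve: CalibrationCurve):
    """Invert the calibration line: (current - intercept) / slope, uM.

    Accepts scalars or arrays.  Values below the intercept yield negative
    concentrations; they are passed through (noise can dip below baseline)
    for the caller to flag.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive to invert")
    out = (np.asarray(current, dtype=float) - curve.intercept) / curve.slope
    return float(out) if np.isscalar(current) else out


def calibrate_electrode(
    concentrations: Sequence[float] = (0.1, 0.5, 1.0),
    n_boluses: int = 1,
    gain: float = 10.0,
    noise: Optional[NoiseModel] = None,
    **kwargs,
) -> CalibrationCurve:
    """Simulate ``n_boluses`` boluses per concentration and fit the line."""
    all_conc: List[float] = []
    currents: List[float] = []
    pre_s = kwargs.get("pre_s", 2.0)
    bolus_duration = kwargs.get("bolus_duration", 5.0)
    mixing_tau = kwargs.get("mixing_tau", 0.3)
    for rep in range(n_boluses):
        rep_noise = (
            replace(noise, rng_seed=noise.rng_seed + 1000 * rep) if noise is not None else None
        )
        for m, c in zip(
            simulate_flow_injection(concentrations, gain=gain, noise=rep_noise, **kwargs),
            concentrations,
        ):
            currents.append(bolus_plateau_current(m, pre_s, bolus_duration, mixing_tau))
            all_conc.append(c)
    return fit_calibration(currents, all_conc)
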