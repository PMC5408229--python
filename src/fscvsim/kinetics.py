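"""Parametric characterization: randomized stimulation protocol and joint
kinetic-model fitting.

The characterization protocol applies a grid of (amplitude, pulse width)
pairs in random order, each for 0.5 or 2.0 s, with a washout of 30 or 300 s
respectively so consecutive responses do not interact (hysteresis-free).
All responses are then fit **jointly** by nonlinear least squares over the
compartment-model parameters — the recruitment sigmoid (da_per_pulse_max,
q50, recruit_slope) is only identifiable across responses spanning several
charges, which is why per-response fits are not offered.  Multistart over
bounded Latin-hypercube initializations (plus one data-driven start) guards
against the multimodality of (q50, recruit_slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .calibration import CalibrationCurve, current_to_concentration
from .processing import background_subtract, extract_timeseries, lowpass_scans
from .stimulus import StimulusTrain
from .subject import (
    KineticParams,
    VirtualSubject,
    simulate_batch,
    simulate_concentration,
)

__all__ = [
    "CharacterizationProtocol",
    "Response",
    "FitResult",
    "run_protocol",
    "fit_kinetics",
    "predict_response",
    "DEFAULT_BOUNDS",
    "FREE_PARAM_NAMES",
]

#: Parameters of the joint fit, in optimization order.
FREE_PARAM_NAMES = ("da_per_pulse_max", "q50", "recruit_slope", "vmax", "km", "k_transfer")

#: Default box bounds for the joint fit (log-uniform multistart draws).
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "da_per_pulse_max": (1e-3, 1.0),
    "q50": (1e-8, 1e-6),
    "recruit_slope": (5e-9, 5e-7),
    "vmax": (0.5, 20.0),
    "km": (0.05, 1.0),
    "k_transfer": (0.2, 20.0),
}

_WASHOUT_FOR_DURATION = {0.5: 30.0, 2.0: 300.0}


@dataclass(frozen=True)
class CharacterizationProtocol:
    """Randomized (amplitude x pulse width) characterization grid.

    ``stim_duration`` must be 0.5 or 2.0 s; the washout is paired to it
    (30 s after short trains, 300 s after long ones).  The presentation
    order is a seeded random permutation of the grid.
    """

    amplitude_grid: tuple
    pulse_width_grid: tuple
    stim_duration: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "amplitude_grid", tuple(float(a) for a in self.amplitude_grid))
        object.__setattr__(self, "pulse_width_grid", tuple(float(p) for p in self.pulse_width_grid))
        if not self.amplitude_grid or not self.pulse_width_grid:
            raise ValueError("amplitude and pulse-width grids must be non-empty")
        if self.stim_duration not in _WASHOUT_FOR_DURATION:
            raise ValueError("stim_duration must be 0.5 or 2.0 seconds")

    @property
    def washout(self) -> float:
        """Stabilization period after each train, seconds (paired to duration)."""
        return _WASHOUT_FOR_DURATION[self.stim_duration]

    def grid(self) -> List[Tuple[float, float]]:
        return [(a, pw) for a in self.amplitude_grid for pw in self.pulse_width_grid]

    def randomized_order(self) -> List[Tuple[float, float]]:
        """The grid in presentation order (a permutation, reproducible from the seed)."""
        cells = self.grid()
        order = np.random.default_rng(self.rng_seed).permutation(len(cells))
        return [cells[i] for i in order]


@dataclass
class Response:
    """One processed stimulation-evoked response.

    ``t``/``conc`` are the model-grid concentration series (uM, baseline
    subtracted, stimulus starting at ``stim_start``).  When the full FSCV
    measurement path was used, ``measured_t``/``measured_conc`` hold the
    calibrated scan-rate series as well.
    """

    amplitude: float
    pulse_width: float
    stim: StimulusTrain
    stim_start: float
    t: np.ndarray
    conc: np.ndarray
    washout_warning: bool = False
    measured_t: Optional[np.ndarray] = None
    measured_conc: Optional[np.ndarray] = None

    @property
    def peak(self) -> float:
        return float(np.max(self.conc))


def _washout_sufficient(params: KineticParams, c_end: float, washout_left: float, tol_conc: float) -> bool:
    """Conservative return-to-baseline check without simulating the washout.

    Time for Michaelis–Menten decay from c_end to tol_conc has the closed
    form ((c_end - tol) + km ln(c_end/tol)) / vmax; three transfer time
    constants are added for the electrode compartment to follow.
    """
    if c_end <= tol_conc:
        return True
    if params.vmax == 0:
        return False
    t_decay = ((c_end - tol_conc) + params.km * np.log(c_end / tol_conc)) / params.vmax
    t_transfer = 3.0 / params.k_transfer if params.k_transfer > 0 else np.inf
    return t_decay + t_transfer <= washout_left


def run_protocol(
    subject: VirtualSubject,
    protocol: CharacterizationProtocol,
    stim_frequency: float = 60.0,
    pre_s: float = 0.5,
    post_s: float = 2.0,
    dt: float = 1e-3,
    conc_noise_frac: float = 0.0,
    noise_seed: int = 0,
    full_fscv: bool = False,
    curve: Optional[CalibrationCurve] = None,
) -> List[Response]:
    """Run the characterization protocol against a virtual subject.

    Each grid cell is presented (in the protocol's randomized order) as a
    current-regulated biphasic train at ``stim_frequency``.  Responses are
    recorded independently — the washout pairing guarantees the subject is
    back at baseline before each train, and a closed-form decay bound flags
    any cell where the washout would *not* have sufficed (a warning record,
    not an exception).

    ``conc_noise_frac`` adds Gaussian noise with SD equal to that fraction
    of each response's peak directly on the concentration series (the
    "processed response" abstraction).  With ``full_fscv=True`` the response
    is instead rendered to a ScanMatrix, background-subtracted, zero-phase
    filtered, read out at the oxidation potential and converted to uM via
    ``curve`` — the full measurement path.
    """
    if full_fscv and curve is None:
        raise ValueError("full_fscv=True requires a calibration curve")
    rng = np.random.default_rng(noise_seed)
    t_grid = np.arange(0.0, pre_s + protocol.stim_duration + post_s + dt / 2, dt)
    responses: List[Response] = []
    for amplitude, pulse_width in protocol.randomized_order():
        stim = StimulusTrain(
            amplitude=amplitude,
            pulse_width=pulse_width,
            frequency=stim_frequency,
            duration=protocol.stim_duration,
        )
        conc = simulate_concentration(subject.params, stim, t_grid, stim_start=pre_s)
        conc = conc - subject.params.baseline
        peak = float(np.max(conc))
        washout_left = protocol.washout - post_s
        warn = not _washout_sufficient(
            subject.params, float(conc[-1]), washout_left, max(0.01 * peak, 1e-12)
        )
        if conc_noise_frac > 0 and peak > 0:
            conc = conc + rng.normal(0.0, conc_noise_frac * peak, size=conc.shape)
        resp = Response(amplitude, pulse_width, stim, pre_s, t_grid.copy(), conc, warn)
        if full_fscv:
            _, _, m = subject.respond(stim, pre_s=pre_s, post_s=post_s)
            n_bg = int(np.sum(m.scan_times < pre_s - 1e-9))
            sub = lowpass_scans(background_subtract(m, (0, max(n_bg, 1))))
            times, series = extract_timeseries(sub, subject.signature.ox_potentials[0], "anodic")
            resp.measured_t = times
            resp.measured_conc = np.asarray(current_to_concentration(series, curve))
        responses.append(resp)
    return responses


@dataclass
class FitResult:
    """Outcome of the joint kinetic fit."""

    params: KineticParams
    r_squared: float
    residual_norm: float
    peak_pairs: List[Tuple[float, float, float, float]]  # (A, PW, observed, predicted)
    n_starts: int
    n_converged: int
    free_names: tuple
    cost: float

    def __post_init__(self):
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


class FitConvergenceError(RuntimeError):
    """All multistarts failed; carries the best partial result."""

    def __init__(self, message: str, partial: Optional[FitResult] = None):
        super().__init__(message)
        self.partial = partial


def _data_driven_start(
    responses: Sequence[Response], frequency: float, duration: float, bounds: Dict
) -> Dict[str, float]:
    """Heuristic initial guess from the measured peak-vs-charge curve."""
    charges = np.array([r.amplitude * r.pulse_width for r in responses])
    peaks = np.array([r.peak for r in responses])
    order = np.argsort(charges)
    charges, peaks = charges[order], peaks[order]
    p_max = max(peaks.max(), 1e-9)
    # released amount ~ DA_p * f * duration; peaks lose ~30% to uptake+transfer
    da0 = 1.3 * p_max / (frequency * duration)
    half = 0.5 * p_max
    above = np.where(peaks >= half)[0]
    q50_0 = charges[above[0]] if above.size else float(np.median(charges))
    beta0 = max((charges.max() - charges.min()) / 8.0, 1e-9)
    guess = {
        "da_per_pulse_max": da0,
        "q50": q50_0,
        "recruit_slope": beta0,
        "vmax": 4.0,
        "km": 0.2,
        "k_transfer": 2.0,
    }
    return {k: float(np.clip(v, *bounds[k])) for k, v in guess.items()}


def fit_kinetics(
    responses: Sequence[Response],
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    n_multistart: int = 16,
    rng_seed: int = 0,
    fixed: Optional[Dict[str, float]] = None,
    max_nfev: int = 400,
) -> FitResult:
    """Joint nonlinear least squares of the compartment model to a set of
    stimulation-evoked responses.

    All responses are fit simultaneously (one parameter vector, residuals
    concatenated); the optimizer is bounded trust-region least squares in
    log10 parameter space, restarted from ``n_multistart`` initializations
    (one data-driven, the rest Latin-hypercube over the log-bounds).
    ``fixed`` pins a subset of :data:`FREE_PARAM_NAMES` to given values.

    Requires >= 4 responses spanning >= 2 amplitudes and >= 2 pulse widths
    (identifiability of the recruitment sigmoid), all on one time grid.
    Returns the best fit with ``r_squared = 1 - SS_res / SS_tot`` over the
    concatenated responses.  Reproducible given (responses, bounds,
    n_multistart, rng_seed).
    """
    responses = list(responses)
    if len(responses) < 4:
        raise ValueError("joint fit requires at least 4 responses")
    if len({r.amplitude for r in responses}) < 2 or len({r.pulse_width for r in responses}) < 2:
        raise ValueError("responses must span >= 2 amplitudes and >= 2 pulse widths")
    t0 = responses[0].t
    for r in responses[1:]:
        if r.t.shape != t0.shape or not np.allclose(r.t, t0, rtol=1e-9, atol=1e-12):
            raise ValueError("all responses must share one time grid")

    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    fixed = dict(fixed or {})
    free_names = tuple(n for n in FREE_PARAM_NAMES if n not in fixed)
    if not free_names:
        raise ValueError("at least one parameter must be free")

    y = np.stack([r.conc for r in responses])
    stims = [r.stim for r in responses]
    starts = [r.stim_start for r in responses]
    frequency = float(np.median([s.frequency for s in stims]))
    duration = float(np.median([s.duration for s in stims]))

    def params_from_theta(theta_log10: np.ndarray) -> KineticParams:
        values = dict(fixed)
        values.update({n: 10.0**v for n, v in zip(free_names, theta_log10)})
        return KineticParams(**values)

    def residual(theta_log10: np.ndarray) -> np.ndarray:
        p = params_from_theta(theta_log10)
        pred = simulate_batch(p, stims, t0, starts) - p.baseline
        return (pred - y).ravel()

    lo = np.log10([bounds[n][0] for n in free_names])
    hi = np.log10([bounds[n][1] for n in free_names])

    smart = _data_driven_start(responses, frequency, duration, bounds)
    x0_list = [np.log10([smart[n] for n in free_names])]
    if n_multistart > 1:
        sampler = qmc.LatinHypercube(d=len(free_names), seed=rng_seed)
        draws = sampler.random(n_multistart - 1)
        for row in draws:
            x0_list.append(lo + row * (hi - lo))

    best = None
    n_converged = 0
    for x0 in x0_list:
        try:
            sol = optimize.least_squares(
                residual,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if sol.success:
            n_converged += 1
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise FitConvergenceError("no multistart produced a usable fit")

    p_best = params_from_theta(best.x)
    pred = simulate_batch(p_best, stims, t0, starts) - p_best.baseline
    ss_res = float(np.sum((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    pairs = [
        (r.amplitude, r.pulse_width, float(np.max(r.conc)), float(np.max(pred[i])))
        for i, r in enumerate(responses)
    ]
    result = FitResult(
        params=p_best,
        r_squared=r2,
        residual_norm=float(np.sqrt(ss_res)),
        peak_pairs=pairs,
        n_starts=len(x0_list),
        n_converged=n_converged,
        free_names=free_names,
        cost=float(best.cost),
    )
    if n_converged == 0:
        raise FitConvergenceError("no multistart converged", partial=result)
    return result


def predict_response(
    params: KineticParams,
    stim: StimulusTrain,
    t_grid: np.ndarray,
    stim_start: float = 0.0,
) -> np.ndarray:
    """Model-predicted measured-compartment series for one train.

    Shares its implementation with the virtual subject
    (:func:`fscvsim.subject.simulate_concentration`), so predictions and
    simulations are identical by construction for equal parameters.
    """
    return simulate_concentration(params, stim, t_grid, stim_start)
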