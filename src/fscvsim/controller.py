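"""ANN inverse controller: predict (amplitude, pulse width) for a target
dopamine response and adapt online from feedback errors.

The controller is a small feed-forward network — two inputs, a single hidden
layer of 7–9 sigmoidal (tanh) units, two linear outputs — trained by batch
gradient descent on mean squared error.  It learns the *inverse* of the
subject: from a desired response descriptor to the stimulation parameters
that evoke it.  The descriptor pair is (peak ΔC, response area over the
stimulation window); both are computed the same way from training responses
and from closed-loop measurements.  Inputs and outputs are affinely
normalized to ≈[−1, 1] over the training data.

During a closed-loop session each stimulation event yields a realized
(descriptor, applied-parameters) pair — a fresh, always-valid sample of the
inverse map — and the weights take a few gradient steps on it.  This online
adaptation is what compensates for electrode sensitivity drift, pH shifts
and other slow changes in the preparation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve, current_to_concentration
from .kinetics import Response
from .processing import background_subtract, extract_timeseries, lowpass_scans
from .stimulus import (
    CURRENT_MAX_A,
    CURRENT_MIN_A,
    PULSE_WIDTH_MAX_S,
    PULSE_WIDTH_MIN_S,
    StimulusTrain,
    snap_to_grid,
    validate_train,
)
from .subject import VirtualSubject

__all__ = [
    "ControllerState",
    "TargetSpec",
    "AdaptationRecord",
    "ClosedLoopEvent",
    "SessionLog",
    "init_controller",
    "ann_forward",
    "forward",
    "train_controller",
    "adapt_online",
    "response_descriptors",
    "target_descriptor",
    "banded_targets",
    "train_inverse_controller",
    "run_closed_loop",
]


@dataclass
class ControllerState:
    """Weights, normalization constants and adaptation history of the ANN.

    Layout: hidden pre-activation ``z = W1 @ x + b1`` (W1 is n_hidden x 2),
    output ``y = W2 @ tanh(z) + b2`` (W2 is 2 x n_hidden), all in normalized
    coordinates.  ``area_per_peak`` maps a scalar peak target to the second
    descriptor; ``max_peak_seen`` is the largest evoked peak in the training
    data (targets above it are flagged unreachable).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    input_center: np.ndarray
    input_halfspan: np.ndarray
    output_center: np.ndarray
    output_halfspan: np.ndarray
    learning_rate: float = 0.05
    rng_seed: int = 0
    area_per_peak: float = 1.0
    max_peak_seen: float = np.inf
    adaptation_log: List["AdaptationRecord"] = field(default_factory=list)

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "ControllerState":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class TargetSpec:
    """A target program: one constant peak, or a band of fractional targets.

    ``band`` bounds are fractions of the maximal stimulation-evoked peak;
    the banded paradigm regulates evoked dopamine between those thresholds.
    """

    kind: str = "constant_peak"
    target_peak: float = 0.0
    band: Tuple[float, float] = (0.15, 0.60)

    def __post_init__(self):
        if self.kind not in ("constant_peak", "banded"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "banded":
            lo, hi = self.band
            if not (0.0 < lo < hi <= 1.0):
                raise ValueError("band must satisfy 0 < low < high <= 1")


@dataclass(frozen=True)
class AdaptationRecord:
    """One adaptation event: target descriptor, evoked descriptor, peak error."""

    target: tuple
    evoked: tuple
    error: float


def init_controller(
    n_hidden: int = 8, rng_seed: int = 0, allow_any_hidden: bool = False
) -> ControllerState:
    """Fresh controller with fan-in-scaled uniform weights in [-0.5, 0.5]."""
    if not allow_any_hidden and not (7 <= n_hidden <= 9):
        raise ValueError("n_hidden must lie in [7, 9] (pass allow_any_hidden=True to override)")
    rng = np.random.default_rng(rng_seed)
    return ControllerState(
        W1=rng.uniform(-0.5, 0.5, (n_hidden, 2)) / np.sqrt(2.0),
        b1=rng.uniform(-0.5, 0.5, n_hidden) / np.sqrt(2.0),
        W2=rng.uniform(-0.5, 0.5, (2, n_hidden)) / np.sqrt(n_hidden),
        b2=rng.uniform(-0.5, 0.5, 2) / np.sqrt(n_hidden),
        input_center=np.zeros(2),
        input_halfspan=np.ones(2),
        output_center=np.zeros(2),
        output_halfspan=np.ones(2),
        rng_seed=rng_seed,
    )


# -- forward pass -----------------------------------------------------------


def _normalize_in(state: ControllerState, x: np.ndarray) -> np.ndarray:
    return (x - state.input_center) / state.input_halfspan


def _denormalize_out(state: ControllerState, yn: np.ndarray) -> np.ndarray:
    return yn * state.output_halfspan + state.output_center


def _forward_normalized(state: ControllerState, xn: np.ndarray):
    z = xn @ state.W1.T + state.b1
    a = np.tanh(z)
    return a @ state.W2.T + state.b2, a


def forward(state: ControllerState, inputs: Sequence[float]) -> np.ndarray:
    """Raw network output (de-normalized, un-snapped): [amplitude_A, pulse_width_s]."""
    x = np.asarray(inputs, dtype=float)
    if x.shape != (2,) or not np.all(np.isfinite(x)):
        raise ValueError("inputs must be two finite descriptor values")
    if not np.all(np.isfinite(state.W1)):
        raise ValueError("controller state is not initialized")
    yn, _ = _forward_normalized(state, _normalize_in(state, x))
    return _denormalize_out(state, yn)


def ann_forward(
    state: ControllerState, inputs: Sequence[float], snap: bool = True
) -> Tuple[float, float]:
    """Predict the (amplitude, pulse width) that should evoke the target
    descriptor; with ``snap=True`` outputs are clamped to the stimulator's
    continuous ranges and the amplitude is snapped to the 10 uA device grid,
    so the prediction always validates."""
    y = forward(state, inputs)
    amplitude, pulse_width = float(y[0]), float(y[1])
    if not snap:
        return amplitude, pulse_width
    amplitude = float(np.clip(amplitude, CURRENT_MIN_A, CURRENT_MAX_A))
    pulse_width = float(np.clip(pulse_width, PULSE_WIDTH_MIN_S, PULSE_WIDTH_MAX_S))
    snapped = snap_to_grid(
        StimulusTrain(amplitude=amplitude, pulse_width=pulse_width, frequency=1.0, duration=0.0)
    )
    return snapped.amplitude, pulse_width


# -- training ---------------------------------------------------------------


def _mse_and_grads(state: ControllerState, xn: np.ndarray, yn: np.ndarray):
    """Batch MSE over all output entries and its analytic gradients."""
    yh, a = _forward_normalized(state, xn)
    err = yh - yn
    mse = float(np.mean(err**2))
    d_y = 2.0 * err / err.size
    g_W2 = d_y.T @ a
    g_b2 = d_y.sum(axis=0)
    d_a = d_y @ state.W2
    d_z = d_a * (1.0 - a**2)
    g_W1 = d_z.T @ xn
    g_b1 = d_z.sum(axis=0)
    return mse, (g_W1, g_b1, g_W2, g_b2)


def _gd_step(state: ControllerState, grads, lr: float) -> None:
    g_W1, g_b1, g_W2, g_b2 = grads
    state.W1 -= lr * g_W1
    state.b1 -= lr * g_b1
    state.W2 -= lr * g_W2
    state.b2 -= lr * g_b2


def _adaptive_gd(
    state: ControllerState,
    xn: np.ndarray,
    yn: np.ndarray,
    n_steps: int,
    lr0: float,
    grow: float = 1.5,
    shrink: float = 0.5,
    min_lr: float = 1e-5,
) -> float:
    """Gradient descent with per-step backtracking on the batch MSE.

    Each step is kept only if it does not increase the loss; otherwise it is
    undone and the step size halved.  Successful steps grow the step size
    again, so correction is fast after a large disturbance (e.g. electrode
    sensitivity change) yet cannot diverge.  Returns the final MSE.
    """
    lr = lr0
    mse, grads = _mse_and_grads(state, xn, yn)
    for _ in range(n_steps):
        _gd_step(state, grads, lr)
        new_mse, new_grads = _mse_and_grads(state, xn, yn)
        if new_mse <= mse:
            mse, grads = new_mse, new_grads
            lr = min(lr * grow, 10.0 * lr0)
        else:
            _gd_step(state, grads, -lr)  # undo
            lr *= shrink
            if lr < min_lr:
                break
    return mse


def _set_normalization(state: ControllerState, X: np.ndarray, Y: np.ndarray) -> None:
    def center_span(v):
        lo, hi = v.min(axis=0), v.max(axis=0)
        span = (hi - lo) / 2.0
        span[span == 0] = 1.0
        return (hi + lo) / 2.0, span

    state.input_center, state.input_halfspan = center_span(X)
    state.output_center, state.output_halfspan = center_span(Y)


def train_controller(
    state: ControllerState,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int = 5000,
    learning_rate: Optional[float] = None,
    set_normalization: bool = True,
):
    """Batch gradient descent on MSE; returns ``(trained_state, mse_curve)``.

    The input state is not modified.  Normalization constants are fit to the
    dataset unless ``set_normalization=False``.  Training is deterministic
    given the initial state.  Raises naming the epoch if the loss diverges
    to NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or Y.shape != X.shape:
        raise ValueError("X and Y must be (n, 2) arrays")
    if X.shape[0] < state.n_hidden:
        raise ValueError(
            f"dataset has {X.shape[0]} examples, fewer than {state.n_hidden} hidden units"
        )
    out = state.copy()
    if set_normalization:
        _set_normalization(out, X, Y)
    lr = out.learning_rate if learning_rate is None else learning_rate
    xn = _normalize_in(out, X)
    yn = (Y - out.output_center) / out.output_halfspan
    curve = np.empty(epochs)
    for epoch in range(epochs):
        mse, grads = _mse_and_grads(out, xn, yn)
        if not np.isfinite(mse):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        curve[epoch] = mse
        _gd_step(out, grads, lr)
    return out, curve


def adapt_online(
    state: ControllerState,
    evoked_descriptor: Sequence[float],
    applied_params: Sequence[float],
    target_descriptor: Sequence[float],
    n_steps: int = 1,
    learning_rate: Optional[float] = None,
    replay: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> ControllerState:
    """Gradient step(s) on the realized sample of the inverse map: the
    measured ``evoked_descriptor`` paired with the ``applied_params`` that
    produced it.  Mutates and returns ``state``; appends exactly one
    :class:`AdaptationRecord` per call.

    ``replay`` optionally supplies recent (descriptor, applied) examples as
    (X, Y) arrays; they are batched with the new sample so adaptation tracks
    the current operating region instead of overfitting one point.  The
    applied parameters should be the raw (un-snapped) network outputs: then
    an event whose evoked response equals its target contributes a
    zero-error example and leaves the weights unchanged.
    """
    evoked = np.asarray(evoked_descriptor, dtype=float)
    target = np.asarray(target_descriptor, dtype=float)
    X = evoked[None, :]
    Y = np.asarray(applied_params, dtype=float)[None, :]
    if replay is not None and len(replay[0]):
        X = np.vstack([np.asarray(replay[0], dtype=float), X])
        Y = np.vstack([np.asarray(replay[1], dtype=float), Y])
    xn = _normalize_in(state, X)
    yn = (Y - state.output_center) / state.output_halfspan
    lr = state.learning_rate if learning_rate is None else learning_rate
    _adaptive_gd(state, xn, yn, n_steps, lr)
    state.adaptation_log.append(
        AdaptationRecord(tuple(target), tuple(evoked), float(evoked[0] - target[0]))
    )
    return state


# -- descriptors and targets ------------------------------------------------


def response_descriptors(
    times: np.ndarray,
    conc: np.ndarray,
    stim_start: float,
    stim_duration: float,
    tail_s: float = 1.0,
) -> np.ndarray:
    """(peak ΔC, area over the stimulation window) from a baseline-subtracted
    concentration series.  The area integrates from stimulus onset to
    ``tail_s`` past train end, capturing the transfer-lagged decay."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    after = times >= stim_start
    peak = float(np.max(conc[after])) if after.any() else float(np.max(conc))
    window = (times >= stim_start) & (times <= stim_start + stim_duration + tail_s)
    area = float(np.trapezoid(conc[window], times[window])) if window.sum() > 1 else 0.0
    return np.array([peak, area])


def target_descriptor(state: ControllerState, target_peak: float) -> np.ndarray:
    """Descriptor pair for a scalar peak target, using the area/peak ratio
    learned from the training responses."""
    return np.array([target_peak, target_peak * state.area_per_peak])


def banded_targets(max_peak: float, low: float = 0.15, high: float = 0.60, n: int = 6) -> np.ndarray:
    """n target peaks evenly spanning [low, high] of the maximal evoked peak."""
    return max_peak * np.linspace(low, high, n)


def train_inverse_controller(
    responses: Sequence[Response],
    n_hidden: int = 8,
    rng_seed: int = 0,
    epochs: int = 100_000,
    learning_rate: float = 0.2,
    n_restarts: int = 3,
    tail_s: float = 1.0,
):
    """Build and train a controller from characterization responses.

    Uses the measured (calibrated FSCV) series when present, otherwise the
    model-grid series.  Training restarts from ``n_restarts`` seeded
    initializations and keeps the one with the lowest final *training* MSE
    (gradient descent on this small network occasionally settles in a poor
    local minimum; selection is by training loss only, mirroring the usual
    per-dataset network selection).  Returns ``(state, mse_curve)``.
    """
    X_rows = []
    Y_rows = []
    for r in responses:
        if r.measured_conc is not None:
            desc = response_descriptors(r.measured_t, r.measured_conc, r.stim_start, r.stim.duration, tail_s)
        else:
            desc = response_descriptors(r.t, r.conc, r.stim_start, r.stim.duration, tail_s)
        X_rows.append(desc)
        Y_rows.append([r.amplitude, r.pulse_width])
    X = np.asarray(X_rows)
    Y = np.asarray(Y_rows)
    trained, curve = None, None
    for restart in range(max(n_restarts, 1)):
        state = init_controller(n_hidden=n_hidden, rng_seed=rng_seed + restart)
        state.learning_rate = learning_rate
        cand, cand_curve = train_controller(state, X, Y, epochs=epochs)
        if curve is None or cand_curve[-1] < curve[-1]:
            trained, curve = cand, cand_curve
    peaks = X[:, 0]
    areas = X[:, 1]
    denom = float(np.sum(peaks**2))
    trained.area_per_peak = float(np.sum(peaks * areas) / denom) if denom > 0 else 1.0
    trained.max_peak_seen = float(peaks.max())
    return trained, curve


# -- closed loop ------------------------------------------------------------


@dataclass(frozen=True)
class ClosedLoopEvent:
    """One stimulation event of a closed-loop session."""

    index: int
    target_peak: float
    amplitude: float
    pulse_width: float
    evoked_peak: float
    error: float
    unreachable: bool
    mse_to_date: float


@dataclass
class SessionLog:
    """Per-event records plus session summary statistics.

    ``regression_r2`` is the squared Pearson correlation between target and
    evoked peaks; ``pooled_r2`` is 1 − SS_err/SS_tot with errors taken
    against the targets (it penalizes any systematic transient, e.g. from a
    miscalibrated start).
    """

    events: List[ClosedLoopEvent]
    final_mse: float
    regression_slope: float
    regression_intercept: float
    regression_r2: float
    pooled_r2: float

    @property
    def targets(self) -> np.ndarray:
        return np.array([e.target_peak for e in self.events])

    @property
    def evoked(self) -> np.ndarray:
        return np.array([e.evoked_peak for e in self.events])


def run_closed_loop(
    subject: VirtualSubject,
    state: ControllerState,
    target_peaks: Sequence[float],
    curve: CalibrationCurve,
    stim_frequency: float = 60.0,
    pre_s: float = 0.5,
    post_s: float = 2.0,
    adapt: bool = True,
    n_adapt_steps: int = 40,
    adapt_window: int = 18,
    adapt_learning_rate: Optional[float] = None,
    tail_s: float = 1.0,
) -> SessionLog:
    """Run a closed-loop session: for each target, predict parameters, apply
    them to the subject, measure the evoked response through the full FSCV
    chain (synthesis → background subtraction → zero-phase filter → oxidation
    readout → calibration), compute the error, and adapt the weights.

    Targets above the largest peak seen in training are flagged
    ``unreachable`` but the loop continues (the network still produces its
    best saturated guess).  Fully reproducible given the subject's noise
    seed and the controller state.
    """
    events: List[ClosedLoopEvent] = []
    sq_errors: List[float] = []
    replay_X: List[np.ndarray] = []
    replay_Y: List[np.ndarray] = []
    for i, target_peak in enumerate(target_peaks):
        target_peak = float(target_peak)
        tdesc = target_descriptor(state, target_peak)
        raw = forward(state, tdesc)
        amplitude, pulse_width = ann_forward(state, tdesc, snap=True)
        stim = StimulusTrain(
            amplitude=amplitude,
            pulse_width=pulse_width,
            frequency=stim_frequency,
            duration=0.5,
        )
        assert not validate_train(stim), "controller emitted an out-of-envelope train"
        unreachable = target_peak > 1.05 * state.max_peak_seen

        if subject.noise is not None:
            subject.noise = replace(subject.noise, rng_seed=subject.noise.rng_seed + 1)
        _, _, m = subject.respond(stim, pre_s=pre_s, post_s=post_s)
        n_bg = int(np.sum(m.scan_times < pre_s - 1e-9))
        sub = lowpass_scans(background_subtract(m, (0, max(n_bg, 1))))
        times, series = extract_timeseries(sub, subject.signature.ox_potentials[0], "anodic")
        conc = np.asarray(current_to_concentration(series, curve))
        edesc = response_descriptors(times, conc, pre_s, stim.duration, tail_s)

        error = float(edesc[0] - target_peak)
        sq_errors.append(error**2)
        if adapt:
            adapt_online(
                state,
                edesc,
                raw,
                tdesc,
                n_steps=n_adapt_steps,
                learning_rate=adapt_learning_rate,
                replay=(np.asarray(replay_X), np.asarray(replay_Y)) if replay_X else None,
            )
            replay_X.append(edesc)
            replay_Y.append(raw)
            if len(replay_X) > adapt_window:
                replay_X.pop(0)
                replay_Y.pop(0)
            # keep the target-descriptor line on the measured (peak, area)
            # manifold: after a sensitivity change the training-time ratio
            # would query the network off the manifold it is adapted on
            peaks_w = np.array([x[0] for x in replay_X])
            areas_w = np.array([x[1] for x in replay_X])
            denom = float(np.sum(peaks_w**2))
            if denom > 0:
                state.area_per_peak = float(np.sum(peaks_w * areas_w) / denom)
        events.append(
            ClosedLoopEvent(
                index=i,
                target_peak=target_peak,
                amplitude=amplitude,
                pulse_width=pulse_width,
                evoked_peak=float(edesc[0]),
                error=error,
                unreachable=unreachable,
                mse_to_date=float(np.mean(sq_errors)),
            )
        )

    targets = np.array([e.target_peak for e in events])
    evoked = np.array([e.evoked_peak for e in events])
    if np.unique(targets).size >= 2:
        reg = stats.linregress(targets, evoked)
        slope, intercept, r2 = float(reg.slope), float(reg.intercept), float(reg.rvalue**2)
    else:
        slope, intercept, r2 = np.nan, np.nan, np.nan
    ss_err = float(np.sum((evoked - targets) ** 2))
    ss_tot = float(np.sum((evoked - evoked.mean()) ** 2))
    pooled = 1.0 - ss_err / ss_tot if ss_tot > 0 else np.nan
    return SessionLog(
        events=events,
        final_mse=float(np.mean(sq_errors)),
        regression_slope=slope,
        regression_intercept=intercept,
        regression_r2=r2,
        pooled_r2=pooled,
    )
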