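"""Stimulator parameter space: train validation, device grid, per-pulse charge.

The stimulation back-end delivers monophasic or biphasic charge-balanced
pulse trains, current-regulated (10 uA – 10 mA in 10 uA steps) or
voltage-regulated (50 mV – 10 V in 10 mV steps), with per-phase pulse widths
between 50 us and 2 ms.  ``validate_train`` never raises — it returns the
list of violated constraints so a caller (or the CLI) can report all of them
at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, NamedTuple

import numpy as np

__all__ = [
    "StimulusTrain",
    "PulseCharge",
    "CURRENT_MIN_A",
    "CURRENT_MAX_A",
    "CURRENT_STEP_A",
    "VOLTAGE_MIN_V",
    "VOLTAGE_MAX_V",
    "VOLTAGE_STEP_V",
    "PULSE_WIDTH_MIN_S",
    "PULSE_WIDTH_MAX_S",
    "validate_train",
    "snap_to_grid",
    "charge_per_pulse",
    "pulse_onset_times",
    "charge_per_phase",
]

CURRENT_MIN_A = 10e-6
CURRENT_MAX_A = 10e-3
CURRENT_STEP_A = 10e-6
VOLTAGE_MIN_V = 50e-3
VOLTAGE_MAX_V = 10.0
VOLTAGE_STEP_V = 10e-3
PULSE_WIDTH_MIN_S = 50e-6
PULSE_WIDTH_MAX_S = 2e-3

_MODES = ("current_regulated", "voltage_regulated")
_POLARITIES = ("monophasic", "biphasic_charge_balanced")


@dataclass(frozen=True)
class StimulusTrain:
    """One stimulus train.

    Parameters
    ----------
    amplitude:
        Amperes in current-regulated mode, volts in voltage-regulated mode.
    pulse_width:
        Seconds per phase.
    frequency:
        Pulse rate, Hz.
    duration:
        Train length, seconds.  A pulse whose onset lands exactly at
        ``duration`` is included (closed interval).
    mode, polarity:
        Regulation mode and pulse polarity.
    onset_delay:
        Milliseconds between the start of an FSCV acquisition and the first
        pulse (the synchronization handle).

    The constructor performs no range validation so that out-of-envelope
    trains can be constructed and passed to :func:`validate_train`.
    """

    amplitude: float
    pulse_width: float
    frequency: float
    duration: float
    mode: str = "current_regulated"
    polarity: str = "biphasic_charge_balanced"
    onset_delay: float = 0.0

    @property
    def phases_per_pulse(self) -> int:
        return 2 if self.polarity == "biphasic_charge_balanced" else 1


def _is_on_grid(value: float, step: float) -> bool:
    k = value / step
    return abs(k - round(k)) < 1e-6


def validate_train(train: StimulusTrain) -> List[str]:
    """Return every violated device constraint (empty list == ok).  Never raises."""
    v: List[str] = []
    if train.mode not in _MODES:
        v.append(f"unknown mode {train.mode!r}")
    if train.polarity not in _POLARITIES:
        v.append(f"unknown polarity {train.polarity!r}")

    if train.mode == "current_regulated":
        if train.amplitude < CURRENT_MIN_A - 1e-12:
            v.append("amplitude below minimum (10 uA)")
        if train.amplitude > CURRENT_MAX_A + 1e-12:
            v.append("amplitude above maximum (10 mA)")
        if not _is_on_grid(train.amplitude, CURRENT_STEP_A):
            v.append("amplitude not a multiple of 10 uA")
    elif train.mode == "voltage_regulated":
        if train.amplitude < VOLTAGE_MIN_V - 1e-12:
            v.append("amplitude below minimum (50 mV)")
        if train.amplitude > VOLTAGE_MAX_V + 1e-9:
            v.append("amplitude above maximum (10 V)")
        if not _is_on_grid(train.amplitude, VOLTAGE_STEP_V):
            v.append("amplitude not a multiple of 10 mV")

    if train.pulse_width < PULSE_WIDTH_MIN_S - 1e-12:
        v.append("pulse width below minimum (50 us)")
    if train.pulse_width > PULSE_WIDTH_MAX_S + 1e-12:
        v.append("pulse width above maximum (2 ms)")

    if train.frequency <= 0:
        v.append("frequency must be positive")
    elif train.frequency * train.pulse_width * train.phases_per_pulse >= 1.0:
        v.append("duty cycle >= 1 (frequency x pulse width x phases)")

    if train.duration < 0:
        v.append("duration must be non-negative")
    return v


def snap_to_grid(train: StimulusTrain) -> StimulusTrain:
    """Round the amplitude to the nearest device step (changes it by <= half a step)."""
    step = CURRENT_STEP_A if train.mode == "current_regulated" else VOLTAGE_STEP_V
    return replace(train, amplitude=round(train.amplitude / step) * step)


class PulseCharge(NamedTuple):
    """Charge bookkeeping for one pulse (current-regulated trains)."""

    per_phase: float  # coulombs delivered by each phase
    net: float  # net charge per pulse; 0 for biphasic charge-balanced


def charge_per_pulse(train: StimulusTrain) -> PulseCharge:
    """Charge per pulse, coulombs.

    Only defined for current-regulated trains: in voltage mode the delivered
    current depends on the (unknown) load impedance.
    """
    if train.mode != "current_regulated":
        raise ValueError("charge per pulse requires a current-regulated train (load impedance unknown)")
    q = train.amplitude * train.pulse_width
    net = 0.0 if train.polarity == "biphasic_charge_balanced" else q
    return PulseCharge(q, net)


def charge_per_phase(amplitude: float, pulse_width: float) -> float:
    """Per-phase charge A x PW, the drive variable of the recruitment sigmoid."""
    return amplitude * pulse_width


def pulse_onset_times(train: StimulusTrain) -> np.ndarray:
    """Onset instants (seconds): ``onset_delay + k / frequency`` for
    ``k = 0 .. floor(duration * frequency)``; strictly increasing.

    A zero-duration train degenerates to a single pulse at the delay.
    """
    if train.frequency <= 0:
        raise ValueError("frequency must be positive")
    if train.duration < 0:
        raise ValueError("duration must be non-negative")
    n = int(np.floor(train.duration * train.frequency + 1e-9))
    return train.onset_delay * 1e-3 + np.arange(n + 1) / train.frequency
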