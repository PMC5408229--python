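"""FSCV applied-potential programs and stimulus–scan synchronization.

Fast-scan cyclic voltammetry (FSCV) sweeps a carbon-fiber microelectrode's
potential at hundreds of V/s along a short piecewise-linear program (a
"scan"), repeated at ~10 Hz, holding the electrode at a resting potential
between scans.  Electrical stimulation delivered during a recording produces
large artifact transients; because the stimulator and the scanner share a
clock, a per-train onset delay can steer every stimulus pulse either into the
inter-scan holding segment or onto applied potentials far from the analyte's
oxidation/reduction peaks.  This module generates the potential programs and
searches for that delay.

Two waveform shapes are supported:

* ``triangular`` — holding → vertex → holding (the standard dopamine ramp,
  e.g. −0.4 V → +1.45 V → −0.4 V at 400 V/s);
* ``n_shaped`` — start → upper vertex → lower vertex → start (used for
  serotonin to mitigate fouling, e.g. +0.2 → +1.0 → −0.1 → +0.2 V).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .stimulus import StimulusTrain, pulse_onset_times

__all__ = [
    "FscvWaveform",
    "ScanSchedule",
    "PulseRecord",
    "triangular_dopamine_waveform",
    "n_shaped_serotonin_waveform",
    "make_waveform",
    "potential_at",
    "sample_times",
    "n_sweep_samples",
    "sweep_potentials",
    "anodic_mask",
    "compute_sync_delay",
    "artifact_overlap_report",
    "overlap_count",
    "check_device_envelope",
    "DEVICE_MAX_SLEW_V_PER_S",
]

#: Maximum applied-potential slew rate the acquisition front-end supports.
DEVICE_MAX_SLEW_V_PER_S = 1200.0


@dataclass(frozen=True)
class FscvWaveform:
    """One channel's applied-potential program.

    Parameters
    ----------
    shape:
        ``"triangular"`` (one vertex) or ``"n_shaped"`` (two vertices).
    holding_potential:
        Resting potential between scans, volts; also the sweep start/end.
    vertex_potentials:
        Turning potentials of the sweep, volts (1 for triangular, 2 for
        N-shaped).
    scan_rate:
        Sweep slew rate, V/s (identical magnitude on every segment).
    repetition_frequency:
        Scan repetition rate, Hz.
    sample_rate:
        Acquisition sampling rate, samples/s.
    """

    shape: str
    holding_potential: float
    vertex_potentials: tuple
    scan_rate: float = 400.0
    repetition_frequency: float = 10.0
    sample_rate: float = 100_000.0

    def __post_init__(self):
        if self.shape not in ("triangular", "n_shaped"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        verts = tuple(float(v) for v in np.atleast_1d(self.vertex_potentials))
        object.__setattr__(self, "vertex_potentials", verts)
        n_expected = 1 if self.shape == "triangular" else 2
        if len(verts) != n_expected:
            raise ValueError(
                f"{self.shape} waveform needs {n_expected} vertex potential(s), got {len(verts)}"
            )
        if self.scan_rate <= 0 or self.repetition_frequency <= 0 or self.sample_rate <= 0:
            raise ValueError("scan_rate, repetition_frequency and sample_rate must be positive")
        if self.scan_duration >= self.period:
            raise ValueError(
                f"scan duration {self.scan_duration * 1e3:.3f} ms does not fit in the "
                f"{self.period * 1e3:.3f} ms repetition period"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def period(self) -> float:
        """Repetition period, seconds."""
        return 1.0 / self.repetition_frequency

    @property
    def potential_path(self) -> tuple:
        """Potentials visited by the sweep, start to end (start == end for both shapes)."""
        return (self.holding_potential, *self.vertex_potentials, self.holding_potential)

    @property
    def scan_duration(self) -> float:
        """Total sweep time, seconds: sum of |potential excursions| / scan_rate."""
        path = np.asarray(self.potential_path)
        return float(np.sum(np.abs(np.diff(path))) / self.scan_rate)

    def breakpoints(self) -> tuple:
        """(times, potentials) of the piecewise-linear program over one period."""
        path = np.asarray(self.potential_path)
        seg_durations = np.abs(np.diff(path)) / self.scan_rate
        times = np.concatenate(([0.0], np.cumsum(seg_durations), [self.period]))
        potentials = np.concatenate((path, [self.holding_potential]))
        return times, potentials

    def segment_slopes(self) -> np.ndarray:
        """dV/dt of each sweep segment plus the trailing holding segment (0)."""
        times, potentials = self.breakpoints()
        dt = np.diff(times)
        with np.errstate(invalid="ignore"):
            slopes = np.diff(potentials) / dt
        slopes[dt == 0] = 0.0
        return slopes


def triangular_dopamine_waveform(
    holding: float = -0.4,
    vertex: float = 1.45,
    scan_rate: float = 400.0,
    repetition_frequency: float = 10.0,
    sample_rate: float = 100_000.0,
) -> FscvWaveform:
    """Standard dopamine ramp.  The switching potential is a parameter (the
    platform has been run with +1.4, +1.45 and +1.5 V vertices)."""
    return FscvWaveform("triangular", holding, (vertex,), scan_rate, repetition_frequency, sample_rate)


def n_shaped_serotonin_waveform(
    start: float = 0.2,
    upper_vertex: float = 1.0,
    lower_vertex: float = -0.1,
    scan_rate: float = 400.0,
    repetition_frequency: float = 10.0,
    sample_rate: float = 100_000.0,
) -> FscvWaveform:
    """N-shaped serotonin program: start → upper → lower → start."""
    return FscvWaveform(
        "n_shaped", start, (upper_vertex, lower_vertex), scan_rate, repetition_frequency, sample_rate
    )


@dataclass(frozen=True)
class ScanSchedule:
    """Start times of consecutive scans (strictly increasing, spaced by the period)."""

    scan_start_times: np.ndarray
    scan_duration: float
    n_scans: int

    @classmethod
    def for_waveform(cls, waveform: FscvWaveform, n_scans: int) -> "ScanSchedule":
        times = np.arange(n_scans) * waveform.period
        return cls(times, waveform.scan_duration, n_scans)


# -- sampling ---------------------------------------------------------------


def _n_period_samples(waveform: FscvWaveform) -> int:
    return int(round(waveform.sample_rate / waveform.repetition_frequency))


def sample_times(waveform: FscvWaveform) -> np.ndarray:
    """Sample instants of one repetition period, seconds."""
    return np.arange(_n_period_samples(waveform)) / waveform.sample_rate


def make_waveform(waveform: FscvWaveform) -> np.ndarray:
    """Sampled potential series for one full period (sweep + holding segment).

    Piecewise linear; |dV/dt| equals ``scan_rate`` on every sweep segment and
    0 on the holding segment.  Length is ``round(sample_rate /
    repetition_frequency)`` samples.
    """
    times, potentials = waveform.breakpoints()
    return np.interp(sample_times(waveform), times, potentials)


def potential_at(waveform: FscvWaveform, time_in_scan):
    """Applied potential at ``time_in_scan`` seconds after scan start.

    Accepts a scalar or array; every time must lie in ``[0, period)``.
    Exact at segment boundaries.
    """
    t = np.asarray(time_in_scan, dtype=float)
    if np.any(t < 0) or np.any(t >= waveform.period):
        raise ValueError("time_in_scan must lie in [0, repetition period)")
    times, potentials = waveform.breakpoints()
    out = np.interp(t, times, potentials)
    return float(out) if np.isscalar(time_in_scan) else out


def n_sweep_samples(waveform: FscvWaveform) -> int:
    """Number of samples whose instant falls inside the sweep window."""
    return int(np.ceil(waveform.scan_duration * waveform.sample_rate - 1e-9))


def sweep_potentials(waveform: FscvWaveform) -> np.ndarray:
    """Potentials at the sweep-window samples (the ScanMatrix potential axis)."""
    n = n_sweep_samples(waveform)
    return potential_at(waveform, np.arange(n) / waveform.sample_rate)


def anodic_mask(waveform: FscvWaveform) -> np.ndarray:
    """Boolean mask over the sweep samples: True where dV/dt > 0.

    A sample lying exactly on a vertex belongs to the following segment.
    """
    n = n_sweep_samples(waveform)
    t = np.arange(n) / waveform.sample_rate
    times, _ = waveform.breakpoints()
    slopes = waveform.segment_slopes()
    # tolerance so a sample nominally on a vertex is not pushed into the
    # preceding segment by roundoff in the breakpoint cumsum
    seg = np.searchsorted(times, t + 1e-12, side="right") - 1
    return slopes[seg] > 0


def check_device_envelope(waveform: FscvWaveform, max_slew: float = DEVICE_MAX_SLEW_V_PER_S) -> None:
    """Raise if the program exceeds the acquisition front-end's slew limit."""
    peak = float(np.max(np.abs(waveform.segment_slopes())))
    if peak > max_slew:
        raise ValueError(f"waveform slew rate {peak:.0f} V/s exceeds device envelope {max_slew:.0f} V/s")


# -- stimulus/scan overlap --------------------------------------------------


@dataclass(frozen=True)
class PulseRecord:
    """Where one stimulus pulse onset lands relative to the scan schedule."""

    pulse_index: int
    time_s: float
    scan_index: int
    in_scan: bool
    potential: Optional[float]  # applied potential at onset; None in holding segment


def artifact_overlap_report(
    stim: StimulusTrain, waveform: FscvWaveform, delay_ms: float = 0.0
) -> list:
    """Per-pulse placement report for a train that starts ``delay_ms`` after scan 0.

    One record per pulse onset in the train.  Potentials are reported only
    for pulses that land inside a scan window; pulses in the holding segment
    are flagged with ``in_scan=False`` and ``potential=None``.
    """
    onsets = pulse_onset_times(replace(stim, onset_delay=delay_ms))
    period = waveform.period
    records = []
    for k, t in enumerate(onsets):
        scan_idx = int(np.floor(t / period + 1e-9))
        rel = max(t - scan_idx * period, 0.0)
        in_scan = rel < waveform.scan_duration - 1e-12
        pot = float(potential_at(waveform, rel)) if in_scan else None
        records.append(PulseRecord(k, float(t), scan_idx, bool(in_scan), pot))
    return records


def _windows_array(avoid_windows: Sequence) -> np.ndarray:
    w = np.atleast_2d(np.asarray(avoid_windows, dtype=float))
    if w.size == 0:
        return w.reshape(0, 2)
    if w.shape[1] != 2 or np.any(w[:, 0] > w[:, 1]):
        raise ValueError("avoid_windows must be (low, high) potential intervals")
    return w


def _overlap_counts_for_delays(
    stim: StimulusTrain, waveform: FscvWaveform, delays_s: np.ndarray, avoid_windows
) -> np.ndarray:
    windows = _windows_array(avoid_windows)
    base = pulse_onset_times(replace(stim, onset_delay=0.0))
    period = waveform.period
    times, potentials = waveform.breakpoints()
    rel = (delays_s[:, None] + base[None, :]) % period
    in_scan = rel < waveform.scan_duration - 1e-12
    pot = np.interp(rel, times, potentials)
    in_window = np.zeros_like(in_scan)
    for lo, hi in windows:
        in_window |= (pot >= lo) & (pot <= hi)
    return (in_scan & in_window).sum(axis=1)


def overlap_counts_over_grid(
    stim: StimulusTrain,
    waveform: FscvWaveform,
    avoid_windows,
    grid_ms: float = 0.1,
):
    """(delays_ms, counts) over the full delay grid spanning one period.

    The same enumeration backs :func:`compute_sync_delay` (argmin) and the
    worst-case phase of a free-running, unsynchronized stimulator (argmax).
    """
    delays = np.arange(0.0, waveform.period, grid_ms * 1e-3)
    counts = _overlap_counts_for_delays(stim, waveform, delays, avoid_windows)
    return delays * 1e3, counts


def overlap_count(
    stim: StimulusTrain, waveform: FscvWaveform, delay_ms: float, avoid_windows
) -> int:
    """Number of pulse onsets landing inside a scan at a potential within any avoid window."""
    return int(
        _overlap_counts_for_delays(stim, waveform, np.array([delay_ms * 1e-3]), avoid_windows)[0]
    )


def compute_sync_delay(
    stim: StimulusTrain,
    waveform: FscvWaveform,
    avoid_windows,
    grid_ms: float = 0.1,
) -> float:
    """Delay (ms) between scan start and the first stimulus pulse that keeps
    artifacts away from the analyte's redox potentials.

    Searches a ``grid_ms`` grid over one repetition period and returns the
    delay minimizing the number of pulse onsets that land inside a scan at an
    applied potential within any avoid window (e.g. ±0.15 V around the
    dopamine oxidation and reduction peaks).  Ties break toward the smallest
    delay; artifact position is judged at pulse onset only.
    """
    delays_ms, counts = overlap_counts_over_grid(stim, waveform, avoid_windows, grid_ms)
    return float(delays_ms[int(np.argmin(counts))])
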