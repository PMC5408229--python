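"""Orchestration: configuration, seed derivation, and the desk-scale demos
(artifact placement and multi-channel recording).

All randomness in a run derives from one top-level seed via
``numpy.random.SeedSequence`` spawning, so every demo and CLI command is
reproducible from its config alone.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .processing import background_subtract, extract_timeseries
from .scanio import ScanMatrix
from .stimulus import StimulusTrain
from .subject import (
    KineticParams,
    NoiseModel,
    VirtualSubject,
    default_rodent_params,
    dopamine_signature,
)
from .waveforms import (
    FscvWaveform,
    artifact_overlap_report,
    overlap_counts_over_grid,
    triangular_dopamine_waveform,
)

__all__ = [
    "derive_seeds",
    "dopamine_avoid_windows",
    "demo_artifact_placement",
    "demo_multichannel",
    "MAX_CHANNELS",
]

#: The acquisition hardware supports up to four simultaneous channels.
MAX_CHANNELS = 4


def derive_seeds(master_seed: int, n: int) -> List[int]:
    """n independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def dopamine_avoid_windows(half_width: float = 0.15) -> List[tuple]:
    """Potential intervals around the dopamine oxidation (+0.6 V) and
    reduction (−0.2 V) peaks that stimulation artifacts must avoid."""
    return [(0.6 - half_width, 0.6 + half_width), (-0.2 - half_width, -0.2 + half_width)]


def demo_artifact_placement(
    frequencies: Sequence[float] = (60.0, 90.0, 130.0),
    amplitude: float = 300e-6,
    pulse_width: float = 500e-6,
    duration: float = 2.0,
    waveform: Optional[FscvWaveform] = None,
    avoid_half_width: float = 0.15,
) -> Dict:
    """Artifact placement with and without stimulus–scan synchronization.

    For each stimulation frequency, counts pulse onsets landing inside a
    scan within ±``avoid_half_width`` V of the dopamine redox potentials.
    An unsynchronized stimulator free-runs against the scan clock, so its
    train phase is arbitrary: the unsynchronized condition reports the
    worst-case phase over the delay grid, the synchronized condition the
    computed optimal delay.  Synchronized counts are never worse, and are
    zero whenever a feasible delay exists.  The report is JSON-serializable.
    """
    waveform = waveform or triangular_dopamine_waveform()
    windows = dopamine_avoid_windows(avoid_half_width)
    report = {
        "waveform": {
            "shape": waveform.shape,
            "holding_potential": waveform.holding_potential,
            "vertex_potentials": list(waveform.vertex_potentials),
            "scan_rate": waveform.scan_rate,
            "repetition_frequency": waveform.repetition_frequency,
        },
        "avoid_windows": [list(w) for w in windows],
        "stimulus": {"amplitude_A": amplitude, "pulse_width_s": pulse_width, "duration_s": duration},
        "frequencies": [],
    }
    for freq in frequencies:
        stim = StimulusTrain(
            amplitude=amplitude, pulse_width=pulse_width, frequency=freq, duration=duration
        )
        delays_ms, counts = overlap_counts_over_grid(stim, waveform, windows)
        i_best = int(np.argmin(counts))
        i_worst = int(np.argmax(counts))
        n_pulses = len(artifact_overlap_report(stim, waveform, 0.0))
        report["frequencies"].append(
            {
                "frequency_hz": freq,
                "n_pulses": n_pulses,
                "unsynchronized_delay_ms": float(delays_ms[i_worst]),
                "unsynchronized_in_window": int(counts[i_worst]),
                "sync_delay_ms": float(delays_ms[i_best]),
                "synchronized_in_window": int(counts[i_best]),
            }
        )
    return report


def demo_multichannel(
    n_channels: int = 4,
    master_seed: int = 0,
    stim: Optional[StimulusTrain] = None,
    base_params: Optional[KineticParams] = None,
    pre_s: float = 0.5,
    post_s: float = 2.0,
):
    """Quasi-simultaneous recording across up to four channels.

    Each channel gets its own kinetic parameters (release scaled per
    channel), electrode gain and noise seed; one stimulus train drives them
    all.  Returns ``(scan_matrices, peak_table)`` where the table lists the
    per-channel peak background-subtracted oxidation current.
    """
    if not (1 <= n_channels <= MAX_CHANNELS):
        raise ValueError(f"channel count must be 1..{MAX_CHANNELS} (device envelope)")
    stim = stim or StimulusTrain(amplitude=300e-6, pulse_width=500e-6, frequency=60.0, duration=0.5)
    base = base_params or default_rodent_params()
    seeds = derive_seeds(master_seed, n_channels)
    release_scale = np.linspace(1.0, 0.55, n_channels)  # electrode distance from the hot spot
    gain_scale = np.linspace(1.0, 0.8, n_channels)
    matrices: List[ScanMatrix] = []
    rows = []
    for ch in range(n_channels):
        params = replace(base, da_per_pulse_max=base.da_per_pulse_max * release_scale[ch])
        subject = VirtualSubject(
            params=params,
            signature=dopamine_signature(gain=800.0 * gain_scale[ch]),
            noise=NoiseModel(rng_seed=seeds[ch]),
            channel_id=f"ch{ch}",
        )
        _, conc, m = subject.respond(stim, pre_s=pre_s, post_s=post_s)
        matrices.append(m)
        n_bg = int(np.sum(m.scan_times < pre_s - 1e-9))
        sub = background_subtract(m, (0, max(n_bg, 1)))
        _, series = extract_timeseries(sub, 0.6, "anodic")
        rows.append(
            {
                "channel": f"ch{ch}",
                "peak_ox_current_nA": float(series.max()),
                "peak_conc_uM": float(conc.max()),
                "noise_seed": seeds[ch],
            }
        )
    return matrices, pd.DataFrame(rows)
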