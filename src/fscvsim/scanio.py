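"""The ScanMatrix recording container and its delimited-text serialization.

A ScanMatrix is the data behind the standard FSCV pseudocolor plot: one row
of current samples per scan, a shared potential axis over the sweep portion
of the waveform, and the scan start times.  The text format is a plain
``key=value`` comment header followed by one whitespace-separated row per
scan (scan time first, then the current samples).  Floats are written with
``repr`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .waveforms import FscvWaveform, anodic_mask, sweep_potentials

__all__ = ["ScanMatrix", "save_scan_matrix", "load_scan_matrix"]

_FORMAT_TAG = "fscvsim-scanmatrix-v1"


@dataclass
class ScanMatrix:
    """An FSCV recording: ``currents[scan, sample]`` in nA plus its axes.

    ``potential_axis`` must match the waveform's sweep samples and
    ``scan_times`` must be spaced by the repetition period; both are checked
    on construction.
    """

    currents: np.ndarray
    potential_axis: np.ndarray
    scan_times: np.ndarray
    waveform: FscvWaveform
    channel_id: str = "ch0"

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        self.potential_axis = np.asarray(self.potential_axis, dtype=float)
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        if self.currents.ndim != 2:
            raise ValueError("currents must be a 2-D (n_scans x n_samples) array")
        n_scans, n_samples = self.currents.shape
        if self.potential_axis.shape != (n_samples,):
            raise ValueError("potential_axis length must match the sample axis")
        if self.scan_times.shape != (n_scans,):
            raise ValueError("scan_times length must match the scan axis")
        if not np.allclose(self.potential_axis, sweep_potentials(self.waveform), atol=1e-9):
            raise ValueError("potential_axis does not match the waveform's sweep samples")
        if n_scans > 1 and not np.allclose(
            np.diff(self.scan_times), self.waveform.period, rtol=1e-9, atol=1e-12
        ):
            raise ValueError("scan_times must be spaced by one repetition period")

    @property
    def n_scans(self) -> int:
        return self.currents.shape[0]

    @property
    def n_samples(self) -> int:
        return self.currents.shape[1]

    def anodic_mask(self) -> np.ndarray:
        """True for samples on rising (anodic) sweep segments."""
        return anodic_mask(self.waveform)

    def with_currents(self, currents: np.ndarray) -> "ScanMatrix":
        """Copy with the current matrix replaced (processing stages use this)."""
        return ScanMatrix(
            np.asarray(currents, dtype=float),
            self.potential_axis.copy(),
            self.scan_times.copy(),
            self.waveform,
            self.channel_id,
        )


def _write_header(out: io.TextIOBase, m: ScanMatrix) -> None:
    w = m.waveform
    out.write(f"# {_FORMAT_TAG}\n")
    out.write(f"# channel_id={m.channel_id}\n")
    out.write(f"# shape={w.shape}\n")
    out.write(f"# holding_potential={w.holding_potential!r}\n")
    out.write("# vertex_potentials=" + ",".join(repr(v) for v in w.vertex_potentials) + "\n")
    out.write(f"# scan_rate={w.scan_rate!r}\n")
    out.write(f"# repetition_frequency={w.repetition_frequency!r}\n")
    out.write(f"# sample_rate={w.sample_rate!r}\n")
    out.write(f"# n_scans={m.n_scans}\n")
    out.write(f"# n_samples={m.n_samples}\n")
    out.write("# columns: scan_time_s current_nA...\n")


def save_scan_matrix(m: ScanMatrix, path) -> None:
    """Write a ScanMatrix as delimited text (bit-exact round trip)."""
    with open(path, "w") as out:
        _write_header(out, m)
        for t, row in zip(m.scan_times, m.currents):
            out.write(repr(float(t)) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def load_scan_matrix(path) -> ScanMatrix:
    """Read a ScanMatrix written by :func:`save_scan_matrix`."""
    header = {}
    rows = []
    times = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {_FORMAT_TAG}":
            raise ValueError(f"{path}: not a {_FORMAT_TAG} file")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            parts = line.split()
            times.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])

    waveform = FscvWaveform(
        shape=header["shape"],
        holding_potential=float(header["holding_potential"]),
        vertex_potentials=tuple(float(v) for v in header["vertex_potentials"].split(",")),
        scan_rate=float(header["scan_rate"]),
        repetition_frequency=float(header["repetition_frequency"]),
        sample_rate=float(header["sample_rate"]),
    )
    currents = np.asarray(rows, dtype=float)
    return ScanMatrix(
        currents,
        sweep_potentials(waveform),
        np.asarray(times, dtype=float),
        waveform,
        header.get("channel_id", "ch0"),
    )
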