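"""The FSCV processing chain: background subtraction, zero-phase filtering,
de-trending, and extraction of time series, voltammograms and redox peaks.

Background subtraction removes the capacitive scan template (mean scan over a
pre-stimulus window); the 1 kHz third-order Butterworth filter is applied
forward-backward within each scan so filtering adds no phase shift; scanwise
de-trending removes slow across-scan drift at each potential sample.  All
stages are linear in the current matrix, and all extraction uses
nearest-sample potential lookup (no interpolation) so values stay
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .scanio import ScanMatrix

__all__ = [
    "background_subtract",
    "zero_phase_lowpass",
    "detrend_scanwise",
    "extract_timeseries",
    "extract_voltammogram",
    "find_redox_peaks",
    "lowpass_scans",
    "process_chain",
    "Voltammogram",
    "RedoxPeaks",
]


def background_subtract(m: ScanMatrix, background_window: Tuple[int, int]) -> ScanMatrix:
    """Subtract the mean scan over ``background_window`` (half-open scan-index
    interval) from every scan.

    The window should precede the stimulus onset.  Scans inside the window
    average to zero at every sample afterwards, by construction.
    """
    i0, i1 = background_window
    if not (0 <= i0 < i1 <= m.n_scans):
        raise ValueError(f"background window [{i0}, {i1}) is empty or out of range")
    template = m.currents[i0:i1].mean(axis=0)
    return m.with_currents(m.currents - template[None, :])


def zero_phase_lowpass(
    x: np.ndarray,
    sample_rate: float,
    cutoff: float = 1000.0,
    order: int = 3,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase shift).

    Edge handling uses reflective padding of three times the filter order.
    The two passes square the magnitude response, so the effective
    attenuation at frequency f is ``1 / (1 + (f / cutoff)^(2 order))``.
    """
    x = np.asarray(x, dtype=float)
    if sample_rate <= 2 * cutoff:
        raise ValueError("sample_rate must exceed twice the cutoff")
    padlen = 3 * order
    if x.shape[-1] <= padlen:
        raise ValueError(f"series length {x.shape[-1]} shorter than filter warm-up ({padlen + 1})")
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def lowpass_scans(
    m: ScanMatrix, cutoff: float = 1000.0, order: int = 3
) -> ScanMatrix:
    """Apply the zero-phase low-pass along each scan's sample axis."""
    return m.with_currents(zero_phase_lowpass(m.currents, m.waveform.sample_rate, cutoff, order))


def _detrend_degree(method) -> int:
    if isinstance(method, int):
        deg = method
    elif method == "linear":
        deg = 1
    elif isinstance(method, str) and method.startswith("polynomial-"):
        deg = int(method.split("-", 1)[1])
    else:
        raise ValueError(f"unknown detrend method {method!r}")
    if deg < 0:
        raise ValueError("polynomial degree must be >= 0")
    return deg


def detrend_scanwise(
    m: ScanMatrix,
    method="linear",
    fit_scans: Optional[Sequence[int]] = None,
) -> ScanMatrix:
    """Remove a slow across-scan trend at each potential sample.

    A polynomial in scan time (degree 1 for ``"linear"``, k for
    ``"polynomial-k"``) is fit per potential sample over ``fit_scans``
    (default: all scans) and subtracted from every scan.  Fitting on pre/
    post-stimulus scans only leaves an evoked transient essentially intact
    while cancelling drift.  ``"polynomial-0"`` reduces to subtracting the
    fit-window mean.
    """
    if m.n_scans < 3:
        raise ValueError("scanwise detrending needs at least 3 scans")
    deg = _detrend_degree(method)
    idx = np.arange(m.n_scans) if fit_scans is None else np.asarray(list(fit_scans), dtype=int)
    if idx.size <= deg:
        raise ValueError(f"{idx.size} fit scans cannot constrain a degree-{deg} polynomial")
    x = m.scan_times[idx]
    coeffs = np.polyfit(x, m.currents[idx, :], deg)  # (deg+1, n_samples)
    trend = np.polynomial.polynomial.polyval(m.scan_times, coeffs[::-1], tensor=True).T
    return m.with_currents(m.currents - trend)


def _sweep_indices(m: ScanMatrix, sweep: str) -> np.ndarray:
    mask = m.anodic_mask()
    if sweep == "anodic":
        idx = np.where(mask)[0]
    elif sweep == "cathodic":
        idx = np.where(~mask)[0]
    else:
        raise ValueError(f"sweep must be 'anodic' or 'cathodic', got {sweep!r}")
    if idx.size == 0:
        raise ValueError(f"waveform has no {sweep} samples")
    return idx


def extract_timeseries(
    m: ScanMatrix, potential: float, sweep: str = "anodic"
) -> Tuple[np.ndarray, np.ndarray]:
    """Current vs scan time at the sample nearest ``potential`` on one sweep.

    Returns ``(scan_times, currents)``.  The requested potential must lie
    within the sweep's sampled range (one sample step of slack is allowed so
    that the exact vertex potential maps to the last sweep sample).
    """
    idx = _sweep_indices(m, sweep)
    pots = m.potential_axis[idx]
    step = m.waveform.scan_rate / m.waveform.sample_rate
    if potential < pots.min() - step or potential > pots.max() + step:
        raise ValueError(
            f"potential {potential:+.3f} V outside the {sweep} sweep range "
            f"[{pots.min():+.3f}, {pots.max():+.3f}] V"
        )
    j = idx[int(np.argmin(np.abs(pots - potential)))]
    return m.scan_times.copy(), m.currents[:, j].copy()


class Voltammogram(NamedTuple):
    """One scan paired with the potential axis and its sweep-direction mask."""

    potential: np.ndarray
    current: np.ndarray
    anodic: np.ndarray


def extract_voltammogram(m: ScanMatrix, scan_index: int) -> Voltammogram:
    """The full cyclic voltammogram of one scan."""
    if not (-m.n_scans <= scan_index < m.n_scans):
        raise IndexError(f"scan index {scan_index} out of range for {m.n_scans} scans")
    return Voltammogram(
        m.potential_axis.copy(), m.currents[scan_index].copy(), m.anodic_mask().copy()
    )


@dataclass(frozen=True)
class RedoxPeaks:
    """Oxidation / reduction peak locations of a background-subtracted CV.

    All fields are None when the voltammogram carries no signal (flat input).
    """

    ox_potential: Optional[float]
    ox_current: Optional[float]
    red_potential: Optional[float]
    red_current: Optional[float]

    @property
    def found(self) -> bool:
        return self.ox_potential is not None


def find_redox_peaks(cv: Voltammogram) -> RedoxPeaks:
    """Peak oxidation (argmax on the anodic sweep) and reduction (argmin on
    the cathodic sweep) of a background-subtracted voltammogram.

    Potentials are reported on the sample grid.  A flat (all-equal) CV
    yields a "no peak" result rather than an exception.
    """
    if np.ptp(cv.current) == 0:
        return RedoxPeaks(None, None, None, None)
    an = np.where(cv.anodic)[0]
    ca = np.where(~cv.anodic)[0]
    j_ox = an[int(np.argmax(cv.current[an]))] if an.size else None
    j_red = ca[int(np.argmin(cv.current[ca]))] if ca.size else None
    return RedoxPeaks(
        float(cv.potential[j_ox]) if j_ox is not None else None,
        float(cv.current[j_ox]) if j_ox is not None else None,
        float(cv.potential[j_red]) if j_red is not None else None,
        float(cv.current[j_red]) if j_red is not None else None,
    )


def process_chain(
    m: ScanMatrix,
    background_window: Tuple[int, int],
    lowpass_cutoff: Optional[float] = 1000.0,
    lowpass_order: int = 3,
    detrend: Optional[str] = None,
    detrend_fit_scans: Optional[Sequence[int]] = None,
) -> ScanMatrix:
    """The standard chain: background subtraction, then the within-scan
    zero-phase low-pass, then (optionally) scanwise de-trending."""
    out = background_subtract(m, background_window)
    if lowpass_cutoff is not None:
        out = lowpass_scans(out, lowpass_cutoff, lowpass_order)
    if detrend is not None:
        out = detrend_scanwise(out, detrend, detrend_fit_scans)
    return out
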