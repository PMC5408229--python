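"""Processing chain: subtraction, zero-phase filtering, de-trending,
extraction, redox-peak identification."""

import numpy as np
import pytest

from fscvsim.processing import (
    Voltammogram,
    background_subtract,
    detrend_scanwise,
    extract_timeseries,
    extract_voltammogram,
    find_redox_peaks,
    lowpass_scans,
    process_chain,
    zero_phase_lowpass,
)
from fscvsim.scanio import ScanMatrix
from fscvsim.subject import (
    dopamine_signature,
    serotonin_signature,
    surface_coverage,
    synthesize_recording,
)
from fscvsim.waveforms import sweep_potentials


def flat_recording(waveform, n_scans=20, value=0.0):
    pots = sweep_potentials(waveform)
    currents = np.full((n_scans, pots.size), value)
    times = np.arange(n_scans) * waveform.period
    return ScanMatrix(currents, pots, times, waveform)


class TestBackgroundSubtract:
    def test_window_scans_average_to_zero(self, triangular, noisy_subject, standard_stim):
        _, _, m = noisy_subject.respond(standard_stim)
        sub = background_subtract(m, (0, 5))
        assert sub.currents[0:5].mean(axis=0) == pytest.approx(np.zeros(m.n_samples), abs=1e-12)

    def test_single_scan_window_maps_that_scan_to_zero(self, triangular, noisy_subject, standard_stim):
        _, _, m = noisy_subject.respond(standard_stim)
        sub = background_subtract(m, (2, 3))
        assert np.all(sub.currents[2] == 0.0)

    def test_empty_window_rejected(self, triangular):
        m = flat_recording(triangular)
        with pytest.raises(ValueError, match="window"):
            background_subtract(m, (5, 5))


class TestZeroPhaseLowpass:
    FS = 100_000.0

    def test_passband_tone_amplitude_and_phase_preserved(self):
        t = np.arange(0, 0.1, 1 / self.FS)
        x = np.sin(2 * np.pi * 100.0 * t)
        y = zero_phase_lowpass(x, self.FS)
        mid = slice(2000, -2000)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (len(x[mid]) - 1)
        assert lag == 0

    def test_stopband_attenuation_matches_squared_butterworth(self):
        f = 10_000.0
        t = np.arange(0, 0.05, 1 / self.FS)
        x = np.sin(2 * np.pi * f * t)
        y = zero_phase_lowpass(x, self.FS, cutoff=1000.0, order=3)
        measured_db = 20 * np.log10(np.max(np.abs(y[1000:-1000])))
        # two passes of |H(f)|^2 = 1 / (1 + (f/fc)^(2n)): -60 dB per pass at 10x fc
        expected_db = -10 * np.log10(1 + (f / 1000.0) ** 6) * 2
        assert measured_db < -30.0
        assert measured_db == pytest.approx(expected_db, abs=3.0)

    def test_constant_series_unchanged(self):
        x = np.full(500, 3.7)
        assert zero_phase_lowpass(x, self.FS) == pytest.approx(x, rel=1e-12)

    def test_symmetric_pulse_peak_not_shifted(self):
        t = np.arange(0, 0.02, 1 / self.FS)
        x = np.exp(-((t - 0.01) ** 2) / (2 * 0.001**2))
        y = zero_phase_lowpass(x, self.FS)
        assert np.argmax(y) == np.argmax(x)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            zero_phase_lowpass(np.ones(8), self.FS)

    def test_insufficient_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="twice the cutoff"):
            zero_phase_lowpass(np.ones(100), 1500.0, cutoff=1000.0)


class TestDetrend:
    def test_pure_linear_drift_removed_exactly(self, triangular):
        m = flat_recording(triangular, n_scans=30)
        drift = 2.5 * m.scan_times[:, None] + 1.0
        m = m.with_currents(m.currents + drift)
        out = detrend_scanwise(m, "linear")
        assert np.max(np.abs(out.currents)) < 1e-9

    def test_transient_preserved_when_fit_excludes_it(self, triangular):
        m = flat_recording(triangular, n_scans=40)
        t = m.scan_times
        transient = np.zeros((40, m.n_samples))
        bump = np.exp(-((t - 2.0) ** 2) / (2 * 0.3**2))
        transient[:, 100] = 10.0 * bump
        drift = 1.3 * t[:, None]
        m = m.with_currents(m.currents + transient + drift)
        fit_scans = [i for i in range(40) if t[i] < 1.0 or t[i] > 3.2]
        out = detrend_scanwise(m, "linear", fit_scans=fit_scans)
        assert out.currents[:, 100].max() == pytest.approx(10.0, rel=0.02)

    def test_degree_zero_equals_mean_subtraction(self, triangular):
        m = flat_recording(triangular, n_scans=10)
        rng = np.random.default_rng(0)
        m = m.with_currents(rng.normal(size=m.currents.shape))
        out = detrend_scanwise(m, "polynomial-0")
        expected = m.currents - m.currents.mean(axis=0)
        assert out.currents == pytest.approx(expected, abs=1e-12)

    def test_too_few_fit_scans_rejected(self, triangular):
        m = flat_recording(triangular, n_scans=10)
        with pytest.raises(ValueError, match="cannot constrain"):
            detrend_scanwise(m, "polynomial-3", fit_scans=[0, 1, 2])


class TestExtraction:
    @pytest.fixture()
    def dopamine_recording(self, triangular):
        t = np.arange(0.0, 3.0, 0.005)
        conc = np.exp(-((t - 1.2) ** 2) / (2 * 0.2**2))
        return t, conc, synthesize_recording(
            t, conc, triangular, dopamine_signature(), noise=None,
            adsorption=None, background_amplitude=150.0,
        )

    def test_vertex_potential_maps_to_last_anodic_sample(self, dopamine_recording):
        _, _, m = dopamine_recording
        sub = background_subtract(m, (0, 3))
        _, series = extract_timeseries(sub, 1.45, "anodic")
        mask = m.anodic_mask()
        last_anodic = np.where(mask)[0][-1]
        assert series == pytest.approx(sub.currents[:, last_anodic])

    def test_holding_potential_maps_to_first_sample(self, dopamine_recording):
        _, _, m = dopamine_recording
        _, series = extract_timeseries(m, -0.4, "anodic")
        assert series == pytest.approx(m.currents[:, 0])

    def test_out_of_range_potential_rejected(self, dopamine_recording):
        _, _, m = dopamine_recording
        with pytest.raises(ValueError, match="outside"):
            extract_timeseries(m, 2.0, "anodic")

    def test_extracted_series_tracks_surface_coverage(self, triangular, rodent_params):
        t = np.arange(0.0, 4.0, 0.005)
        conc = 0.8 * np.exp(-((t - 1.0) ** 2) / (2 * 0.25**2))
        ads = rodent_params.adsorption()
        m = synthesize_recording(
            t, conc, triangular, dopamine_signature(), noise=None, adsorption=ads
        )
        sub = background_subtract(m, (0, 3))
        times, series = extract_timeseries(sub, 0.6, "anodic")
        gamma = np.interp(times, t, surface_coverage(t, conc, ads))
        rho = np.corrcoef(series, gamma)[0, 1]
        assert rho > 0.9999

    def test_voltammogram_roundtrip_and_bounds(self, dopamine_recording):
        _, _, m = dopamine_recording
        cv = extract_voltammogram(m, 5)
        assert cv.potential == pytest.approx(m.potential_axis)
        assert cv.current == pytest.approx(m.currents[5])
        cv.current[:] = 0.0  # a copy: the matrix must be untouched
        assert np.any(m.currents[5] != 0.0)
        with pytest.raises(IndexError):
            extract_voltammogram(m, m.n_scans)


class TestRedoxPeaks:
    def make_cv(self, waveform, signature, amplitude=1.0):
        t = np.arange(0.0, 1.0, 0.01)
        m = synthesize_recording(
            t, np.full_like(t, amplitude), waveform, signature, noise=None,
            adsorption=None, background_amplitude=0.0,
        )
        return extract_voltammogram(m, 2)

    def test_dopamine_signature_recovered(self, triangular):
        pk = find_redox_peaks(self.make_cv(triangular, dopamine_signature()))
        dv = triangular.scan_rate / triangular.sample_rate
        assert abs(pk.ox_potential - 0.6) <= dv
        assert abs(pk.red_potential - -0.2) <= dv
        assert pk.ox_current > 0 > pk.red_current

    def test_serotonin_on_n_waveform(self, n_shaped):
        pk = find_redox_peaks(self.make_cv(n_shaped, serotonin_signature()))
        dv = n_shaped.scan_rate / n_shaped.sample_rate
        assert abs(pk.ox_potential - 0.6) <= dv
        assert abs(pk.red_potential - -0.1) <= 2 * dv  # red peak sits at the sweep edge

    def test_flat_cv_reports_no_peak(self, triangular):
        n = sweep_potentials(triangular).size
        cv = Voltammogram(sweep_potentials(triangular), np.zeros(n), np.ones(n, dtype=bool))
        pk = find_redox_peaks(cv)
        assert not pk.found and pk.ox_potential is None

    def test_sign_flip_swaps_extrema(self, triangular):
        cv = self.make_cv(triangular, dopamine_signature())
        flipped = Voltammogram(cv.potential, -cv.current, cv.anodic)
        pk, fpk = find_redox_peaks(cv), find_redox_peaks(flipped)
        an, ca = cv.anodic, ~cv.anodic
        assert fpk.ox_current == pytest.approx(-np.min(cv.current[an]))
        assert fpk.red_current == pytest.approx(-np.max(cv.current[ca]))


class TestChainLinearity:
    def test_chain_is_linear_in_the_current_matrix(self, triangular):
        rng = np.random.default_rng(3)
        m = flat_recording(triangular, n_scans=15)
        X = rng.normal(size=m.currents.shape)
        Y = rng.normal(size=m.currents.shape)
        a, b = 2.0, -0.7

        def chain(c):
            out = process_chain(m.with_currents(c), (0, 4), detrend="linear")
            return out.currents

        lhs = chain(a * X + b * Y)
        rhs = a * chain(X) + b * chain(Y)
        assert lhs == pytest.approx(rhs, abs=1e-9)
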