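"""Virtual subject: compartment kinetics, recruitment, surface model,
recording synthesis."""

from dataclasses import replace

import numpy as np
import pytest

from fscvsim.processing import background_subtract
from fscvsim.stimulus import StimulusTrain
from fscvsim.subject import (
    KineticParams,
    NoiseModel,
    SurfaceAdsorption,
    VirtualSubject,
    dopamine_signature,
    dose_response_surface,
    langmuir_steady_state,
    recruitment_per_pulse,
    simulate_compartments,
    simulate_concentration,
    surface_coverage,
    synthesize_recording,
)
from fscvsim.waveforms import sweep_potentials


def grid(t_end, dt=5e-4):
    return np.arange(0.0, t_end + dt / 2, dt)


class TestRecruitment:
    def test_zero_charge_zero_release(self, rodent_params):
        assert recruitment_per_pulse(rodent_params, 0.0, 500e-6) == 0.0

    def test_saturates_at_da_max(self, rodent_params):
        da = recruitment_per_pulse(rodent_params, 10e-3, 2e-3)  # q >> q50
        assert da == pytest.approx(rodent_params.da_per_pulse_max, rel=1e-6)

    def test_monotone_in_charge(self, rodent_params):
        qs = np.logspace(-9, -6, 40)
        vals = [recruitment_per_pulse(rodent_params, q / 500e-6, 500e-6) for q in qs]
        assert np.all(np.diff(vals) > 0)


class TestKinetics:
    def test_zero_amplitude_stays_at_baseline(self, rodent_params):
        p = replace(rodent_params, baseline=0.05)
        stim = StimulusTrain(0.0, 500e-6, 60.0, 0.5)
        c = simulate_concentration(p, stim, grid(2.0))
        assert np.all(c == pytest.approx(0.05))

    def test_zero_order_decay_when_saturated(self):
        # C >> km: uptake pinned at vmax, so the release compartment decays
        # linearly at slope -vmax after the train
        p = KineticParams(da_per_pulse_max=1.0, vmax=4.0, km=0.01, k_transfer=2.0)
        stim = StimulusTrain(500e-6, 1e-3, 60.0, 0.5)
        t = grid(2.0, 2.5e-4)
        c_u, _ = simulate_compartments(p, stim, t)
        seg = (t > 0.6) & (t < 0.9)  # well above km throughout
        assert c_u[seg].min() > 50 * p.km
        slopes = np.gradient(c_u[seg], t[seg])
        assert slopes == pytest.approx(-p.vmax, rel=0.01)

    def test_integrator_converges_under_step_halving(self, rodent_params, standard_stim):
        peaks = {}
        for dt in (1e-3, 5e-4, 2.5e-4):
            c = simulate_concentration(rodent_params, standard_stim, grid(3.0, dt))
            peaks[dt] = c.max()
        assert abs(peaks[5e-4] - peaks[2.5e-4]) / peaks[2.5e-4] < 1e-3
        assert abs(peaks[1e-3] - peaks[5e-4]) / peaks[5e-4] < 1e-3

    def test_non_negative_and_returns_to_baseline(self, rodent_params, standard_stim):
        c = simulate_concentration(rodent_params, standard_stim, grid(8.0))
        assert np.all(c >= 0)
        peak = c.max()
        assert c[-1] < 0.01 * peak  # back within 1% of baseline given time

    def test_rejects_nonuniform_or_coarse_grid(self, rodent_params, standard_stim):
        with pytest.raises(ValueError, match="uniform"):
            simulate_concentration(rodent_params, standard_stim, np.array([0.0, 0.001, 0.003]))
        with pytest.raises(ValueError, match="1 ms"):
            simulate_concentration(rodent_params, standard_stim, grid(1.0, 2e-3))

    def test_fast_transfer_approaches_single_compartment_decay(self):
        # k_transfer -> inf: C_m tracks C_u; in the low-concentration tail the
        # decay is exponential with rate vmax/km
        p = KineticParams(da_per_pulse_max=0.02, vmax=2.0, km=0.5, k_transfer=200.0)
        stim = StimulusTrain(300e-6, 500e-6, 60.0, 0.3)
        t = grid(4.0, 2.5e-4)
        c_u, c_m = simulate_compartments(p, stim, t)
        assert np.max(np.abs(c_u - c_m)) < 0.03 * c_u.max()
        tail = (t > 2.0) & (c_m > 1e-6)
        rate = -np.gradient(np.log(c_m[tail]), t[tail])
        assert np.median(rate) == pytest.approx(p.vmax / p.km, rel=0.05)

    def test_peak_monotone_in_duration(self, rodent_params):
        peaks = []
        for dur in (0.1, 0.3, 0.5, 1.0, 2.0):
            stim = StimulusTrain(300e-6, 500e-6, 60.0, dur)
            peaks.append(simulate_concentration(rodent_params, stim, grid(dur + 2.0)).max())
        assert np.all(np.diff(peaks) > 0)


class TestDoseResponse:
    def test_surface_monotone_and_saturating(self, rodent_params, standard_stim):
        amps = [50e-6, 150e-6, 300e-6, 600e-6, 1.2e-3]
        pws = [1e-4, 3e-4, 1e-3, 2e-3]
        surf = dose_response_surface(rodent_params, amps, pws, standard_stim)
        assert surf.shape == (5, 4)
        assert np.all(np.diff(surf, axis=0) >= -1e-12)
        assert np.all(np.diff(surf, axis=1) >= -1e-12)
        # low-charge corner ~0, high-charge corner within 5% of the DA_p-max peak
        assert surf[0, 0] < 0.05 * surf[-1, -1]
        sat = replace(standard_stim, amplitude=amps[-1], pulse_width=pws[-1])
        c_max = simulate_concentration(
            replace(rodent_params, q50=0.0, recruit_slope=1e-12), sat, grid(3.0)
        ).max()
        assert surf[-1, -1] == pytest.approx(c_max, rel=0.05)

    def test_empty_grid_rejected(self, rodent_params, standard_stim):
        with pytest.raises(ValueError):
            dose_response_surface(rodent_params, [], [1e-4], standard_stim)


class TestSurface:
    def test_constant_concentration_sits_at_langmuir_equilibrium(self):
        ads = SurfaceAdsorption(k_ads=0.3, k_des=1.5, gamma_max=2.0)
        t = np.arange(0.0, 5.0, 0.01)
        c = np.full_like(t, 0.8)
        gamma = surface_coverage(t, c, ads)
        expected = langmuir_steady_state(ads, 0.8)
        assert gamma == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.0 * 0.3 * 0.8 / (0.3 * 0.8 + 1.5))

    def test_coverage_bounded_by_capacity(self, rodent_params, standard_stim):
        t = grid(3.0)
        c = simulate_concentration(rodent_params, standard_stim, t)
        gamma = surface_coverage(t, c, rodent_params.adsorption())
        assert np.all(gamma >= 0) and np.all(gamma <= rodent_params.gamma_max)


class TestSynthesis:
    def test_zero_concentration_zero_noise_subtracts_to_zero(self, triangular):
        t = np.arange(0.0, 2.0, 0.01)
        m = synthesize_recording(t, np.zeros_like(t), triangular, dopamine_signature(), noise=None)
        sub = background_subtract(m, (0, 5))
        assert np.max(np.abs(sub.currents)) == pytest.approx(0.0, abs=1e-12)

    def test_equilibrium_ox_peak_equals_langmuir_current(self, triangular):
        sig = dopamine_signature(gain=500.0)
        ads = SurfaceAdsorption(0.2, 2.0, 1.0)
        t = np.arange(0.0, 2.0, 0.01)
        c = np.full_like(t, 0.5)
        m = synthesize_recording(
            t, c, triangular, sig, noise=None, adsorption=ads, background_amplitude=0.0
        )
        expected = sig.gain * 1.0 * 0.2 * 0.5 / (0.2 * 0.5 + 2.0)
        j = np.argmin(np.abs(sweep_potentials(triangular) - 0.6))
        assert m.currents[:, j] == pytest.approx(expected, rel=1e-9)

    def test_fixed_seed_bit_identical(self, triangular, standard_stim):
        subj1 = VirtualSubject(noise=NoiseModel(white_sd=1.0, rng_seed=7))
        subj2 = VirtualSubject(noise=NoiseModel(white_sd=1.0, rng_seed=7))
        _, _, m1 = subj1.respond(standard_stim)
        _, _, m2 = subj2.respond(standard_stim)
        assert np.array_equal(m1.currents, m2.currents)

    def test_signature_peaks_land_on_stated_potentials(self, triangular):
        t = np.arange(0.0, 1.0, 0.01)
        c = np.full_like(t, 1.0)
        m = synthesize_recording(
            t, c, triangular, dopamine_signature(), noise=None, background_amplitude=0.0
        )
        pots = m.potential_axis
        mask = m.anodic_mask()
        row = m.currents[2]
        dv = triangular.scan_rate / triangular.sample_rate
        ox = pots[np.where(mask)[0][np.argmax(row[mask])]]
        red = pots[np.where(~mask)[0][np.argmin(row[~mask])]]
        assert abs(ox - 0.6) <= dv
        assert abs(red - -0.2) <= dv

    def test_artifact_spikes_land_at_pulse_samples(self, triangular):
        t = np.arange(0.0, 1.0, 0.01)
        noise = NoiseModel(white_sd=0.0, artifact_amplitude=123.0, rng_seed=0)
        m = synthesize_recording(
            t, np.zeros_like(t), triangular, dopamine_signature(), noise=noise,
            artifact_times=[0.0025, 0.150, 0.2085],  # scan 0 sweep, scan 1 holding, scan 2 sweep
            background_amplitude=0.0,
        )
        assert m.currents[0, 250] == pytest.approx(123.0)
        assert m.currents[2, int(round(0.0085 * 1e5))] == pytest.approx(123.0)
        assert np.count_nonzero(m.currents) == 2  # the holding-segment pulse leaves no sample

    def test_signature_outside_waveform_range_rejected(self, triangular):
        from fscvsim.subject import adenosine_signature

        t = np.arange(0.0, 1.0, 0.01)
        with pytest.raises(ValueError, match="outside the"):
            synthesize_recording(t, np.zeros_like(t), triangular, adenosine_signature(), noise=None)

    def test_drift_grows_linearly_at_ox_potential(self, triangular):
        t = np.arange(0.0, 60.0, 0.1)
        noise = NoiseModel(white_sd=0.0, drift_rate=6.0, rng_seed=0)  # nA / min
        m = synthesize_recording(
            t, np.zeros_like(t), triangular, dopamine_signature(), noise=noise
        )
        j = np.argmin(np.abs(m.potential_axis - 0.6))
        drift = m.currents[:, j] - m.currents[0, j]
        assert drift[-1] == pytest.approx(6.0 * m.scan_times[-1] / 60.0, rel=1e-9)


def test_accelerated_and_reference_integrators_agree():
    from fscvsim import _accel

    release = np.zeros((3, 1500))
    release[:, 100:700] = np.array([[1.0], [2.5], [6.0]])
    ref = _accel._integrate_py(release, 5e-4, 4.0, 0.2, 2.0)
    fast = _accel.integrate_release_reuptake(release, 5e-4, 4.0, 0.2, 2.0)
    assert np.allclose(ref[0], fast[0], atol=1e-12)
    assert np.allclose(ref[1], fast[1], atol=1e-12)
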