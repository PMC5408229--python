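"""Shared fixtures: waveforms, subjects, calibration, and one trained
controller (session-scoped — training is the expensive step)."""

import numpy as np
import pytest

from fscvsim.calibration import (
    bolus_plateau_current,
    fit_calibration,
    simulate_flow_injection,
)
from fscvsim.controller import train_inverse_controller
from fscvsim.kinetics import CharacterizationProtocol, run_protocol
from fscvsim.stimulus import StimulusTrain
from fscvsim.subject import NoiseModel, VirtualSubject, default_rodent_params
from fscvsim.waveforms import n_shaped_serotonin_waveform, triangular_dopamine_waveform


@pytest.fixture(scope="session")
def triangular():
    return triangular_dopamine_waveform()


@pytest.fixture(scope="session")
def n_shaped():
    return n_shaped_serotonin_waveform()


@pytest.fixture(scope="session")
def rodent_params():
    return default_rodent_params()


@pytest.fixture()
def quiet_subject():
    """Noiseless subject: deterministic synthesis for oracle comparisons."""
    return VirtualSubject(noise=None)


@pytest.fixture()
def noisy_subject():
    return VirtualSubject(noise=NoiseModel(white_sd=0.5, rng_seed=42))


@pytest.fixture(scope="session")
def standard_stim():
    return StimulusTrain(amplitude=300e-6, pulse_width=500e-6, frequency=60.0, duration=0.5)


def effective_linear_gain(subject: VirtualSubject) -> float:
    """Low-coverage slope of the Langmuir electrode, nA/uM."""
    p = subject.params
    return subject.signature.gain * p.gamma_max * p.k_ads / p.k_des


@pytest.fixture(scope="session")
def session_calibration():
    """Calibration curve for the default electrode model (noisy boluses)."""
    subject = VirtualSubject(noise=None)
    gain = effective_linear_gain(subject)
    ms = simulate_flow_injection(
        [0.1, 0.5, 1.0], gain=gain, noise=NoiseModel(white_sd=0.5, rng_seed=11)
    )
    return fit_calibration([bolus_plateau_current(m) for m in ms], [0.1, 0.5, 1.0])


@pytest.fixture(scope="session")
def staircase_responses(session_calibration):
    """16-point charge-staircase characterization through the full FSCV path."""
    subject = VirtualSubject(noise=NoiseModel(white_sd=0.5, rng_seed=42))
    amps = np.logspace(np.log10(100e-6), np.log10(500e-6), 16)
    pws = np.logspace(np.log10(100e-6), np.log10(1000e-6), 16)
    responses = []
    for a, pw in zip(amps, pws):
        proto = CharacterizationProtocol((a,), (pw,), 0.5, rng_seed=0)
        responses += run_protocol(
            subject, proto, full_fscv=True, curve=session_calibration
        )
    return responses


@pytest.fixture(scope="session")
def trained_controller(staircase_responses):
    state, mse_curve = train_inverse_controller(staircase_responses, rng_seed=1)
    return state, mse_curve
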