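import numpy as np
import pytest

from patchseq.ephys import StimulusProtocol
from patchseq.synthetic import APShape, TraceSpec, generate_sweep_set


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol(
        current_steps_pA=tuple(float(c) for c in range(-200, 401, 20)))


@pytest.fixture(scope="session")
def regular_firing_cell(protocol):
    """Noiseless cell with regular spike trains from 120 pA upward and a
    planted sag/rebound on the hyperpolarizing sweeps."""
    spikes = {}
    for c in range(120, 401, 20):
        n = (c - 100) // 20
        spikes[float(c)] = list(0.11 + np.linspace(0.0, 0.45, n))
    spec = TraceSpec(
        resting_potential_mV=-70.0, input_resistance_MOhm=100.0,
        membrane_tau_ms=20.0, sag_amplitude_mV=5.0, rebound_mV=3.0,
        spike_times_s=spikes, ap_shape=APShape(), noise_sd_mV=0.0, seed=1)
    sweep_set, truth = generate_sweep_set(spec, protocol)
    return sweep_set, truth, spec
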