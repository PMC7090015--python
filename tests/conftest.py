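import numpy as np
import pytest

import erflnp as E


@pytest.fixture(scope="session")
def stimulus():
    """Default 5 s, 10 kHz stimulus (seed 0)."""
    stim, cmd = E.generate_stimulus(E.StimulusConfig(seed=0))
    return stim


@pytest.fixture(scope="session")
def voltage_command():
    stim, cmd = E.generate_stimulus(E.StimulusConfig(seed=0))
    return cmd


@pytest.fixture(scope="session")
def whitened_bundle(stimulus):
    """(ensemble, operator, whitened trace) for the default stimulus."""
    ens = E.extract_snippets(stimulus)
    op = E.compute_whitening_operator(ens)
    white = E.whiten_stimulus(stimulus, op)
    return ens, op, white


@pytest.fixture(scope="session")
def biphasic_neuron(stimulus):
    return E.make_archetype_neuron("biphasic", stimulus)


@pytest.fixture(scope="session")
def biphasic_trains(biphasic_neuron, stimulus):
    return E.simulate_lnp_spikes(biphasic_neuron, stimulus, n_repetitions=5,
                                 seed=42)


def cosine(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
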