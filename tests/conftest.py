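import numpy as np
import pytest

from rgcpipe import protocols, synthdata


@pytest.fixture(scope="session")
def flicker_300s():
    """The standard 5-min, 60 Hz binary flicker used by the LN analyses."""
    return protocols.make_random_flicker(60.0, 300.0, seed=1)


@pytest.fixture(scope="session")
def awake_preset():
    return synthdata.make_condition_preset("awake")


@pytest.fixture(scope="session")
def awake_cell(awake_preset):
    """One reproducible awake LN neuron."""
    return synthdata.sample_ln_neuron(awake_preset, seed=42)


def make_poisson_train(rate_hz, duration_s, seed=0, n_trials=1):
    """Homogeneous Poisson spike train (helper shared across test modules)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s * n_trials)
    times = np.sort(rng.uniform(0, duration_s * n_trials, size=n))
    return synthdata.SpikeTrain(
        unit_id="poisson",
        times=times,
        t_stop=duration_s * n_trials,
        n_trials=n_trials,
        trial_duration_s=duration_s,
    )
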