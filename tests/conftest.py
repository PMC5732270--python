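import numpy as np
import pytest

from oddball.simulate import SynthNeuronParams, build_sequences, simulate_neuron
from oddball.stimgen import make_tone_grid


@pytest.fixture(scope="session")
def grid():
    return make_tone_grid(5000.0, 0.5)


@pytest.fixture(scope="session")
def pc_recording(grid):
    """One predictive-coding neuron with the full five-sequence protocol."""
    params = SynthNeuronParams(pe_gain=0.8, seed=42)
    seqs = build_sequences(grid, seed=42)
    return simulate_neuron(params, seqs, seed=42)


def poisson_raster(rate_hz, n_trials, rng, window=(-75.0, 250.0)):
    """Homogeneous-Poisson trial raster as a list of spike-time arrays."""
    lo, hi = window
    dur_s = (hi - lo) / 1000.0
    trials = []
    for _ in range(n_trials):
        n = rng.poisson(rate_hz * dur_s)
        trials.append(np.sort(rng.uniform(lo, hi, size=n)))
    return trials
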