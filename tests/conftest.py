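import numpy as np
import pytest

from iplscan import synth
from iplscan.stimulus import generate_chirp


@pytest.fixture(scope="session")
def stim():
    return generate_chirp()


@pytest.fixture(scope="session")
def noisy_dataset(stim):
    """Moderate-noise synthetic dataset: 60 ROIs, 4 batches, 4 repeats."""
    cfg = synth.PopulationConfig(noise_sigma=0.5, psi_sd=0.15)
    rois, truth = synth.sample_population(60, 4, cfg, seed=11)
    traces = synth.simulate_traces(rois, truth, stim, seed=12)
    table = synth.population_table(rois)
    Y = traces.repeats.mean(axis=1)
    return {"rois": rois, "truth": truth, "traces": traces, "table": table, "Y": Y}


@pytest.fixture(scope="session")
def rendered_movie(stim):
    """A default-geometry movie with 30 planted in-range ROIs at high SNR."""
    cfg = synth.PopulationConfig(noise_sigma=0.1, psi_sd=0.15)
    rois, truth = synth.sample_population(30, 1, cfg, seed=1)
    traces = synth.simulate_traces(rois, truth, stim, repeats=4, seed=2)
    movie, mtruth = synth.render_movie(traces, rois, seed=3)
    return {"movie": movie, "mtruth": mtruth, "rois": rois, "traces": traces}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
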