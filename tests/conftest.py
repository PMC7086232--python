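import numpy as np
import pytest

from honpipe import synthgen
from honpipe.core import TraceMatrix
from honpipe.traces import moving_average, neuropil_correct, zscore_matrix


def preprocess(fluor, rate=10.0):
    """Standard chain: neuropil subtraction, 3-frame smoothing, z-score."""
    corrected = neuropil_correct(fluor.traces.values, fluor.neuropil)
    smoothed = moving_average(corrected, 3)
    return zscore_matrix(TraceMatrix(smoothed, rate=rate, kind="raw"))


@pytest.fixture(scope="session")
def medium_session():
    """One synthetic recording shared by read-only tests: 60 cells,
    ~30 locomotion bouts, default noise regime."""
    return synthgen.simulate_session(duration=2600.0, rate=10.0, n_cells=60, bout_rate=1.0, seed=7)


@pytest.fixture(scope="session")
def medium_z(medium_session):
    return preprocess(medium_session.fluor)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
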