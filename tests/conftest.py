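import numpy as np
import pytest

from nmrpath import synthdata as syn


@pytest.fixture
def small_library():
    """Five disjoint single-peak metabolites on a coarse-friendly linewidth."""
    return syn.make_metabolite_library(5, seed=3, max_peaks=1, disjoint=True, halfwidth=0.008)


@pytest.fixture
def quiet_design():
    """Zero-noise, zero-jitter two-group design for exact rendering checks."""
    return syn.SimulationDesign(
        group_sizes={"A": 4, "B": 4},
        noise_sd=0.0,
        jitter_sd=0.0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
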