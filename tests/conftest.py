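import numpy as np
import pytest

from trackseq import (
    SimConfig,
    build_pairs,
    default_seal_like_config,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def fixture_tracks():
    """The package's reference benchmark dataset: 10 individuals x 300
    fixes from the seal-like preset, seed 7."""
    return simulate_tracks(default_seal_like_config(seed=7))


@pytest.fixture(scope="session")
def small_tracks():
    """A quick dataset for unit tests: 6 individuals x 60 fixes."""
    return simulate_tracks(SimConfig(n_individuals=6, n_steps=60, seed=11))


@pytest.fixture(scope="session")
def small_pairs(small_tracks):
    return build_pairs(small_tracks, t_in=7, t_out=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
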