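"""Shared fixtures: expensive synthetic runs are computed once per session."""
import numpy as np
import pytest

from flyvnc.registration import correct_two_channel
from flyvnc.synthetic import ConnectiveMovieSpec, generate_connective_movie
from flyvnc.workflow import PipelineConfig, run_caffeine_pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def moving_movie():
    """A small noisy movie with rigid + non-rigid motion and its truth."""
    spec = ConnectiveMovieSpec(
        n_frames=8, motion_amplitude=4.0, nonrigid_amplitude=1.5,
        noise_sd=2.0, seed=21,
    )
    red, green, truth = generate_connective_movie(spec)
    return spec, red, green, truth


@pytest.fixture(scope="session")
def corrected_movie(moving_movie):
    _, red, green, truth = moving_movie
    red_c, green_c, fields = correct_two_channel(red, green)
    return red_c, green_c, fields, truth


@pytest.fixture(scope="session")
def caffeine_results():
    """One full synthetic caffeine study (shared across tests)."""
    return run_caffeine_pipeline(PipelineConfig(seed=0))
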