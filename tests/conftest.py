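import numpy as np
import pytest

from budtrack.pipeline import _train_default_classifiers
from budtrack.simulate import SimParams, simulate_colony
from budtrack.targets import optimize_size_boundaries


@pytest.fixture(scope="session")
def small_movie():
    """A short colony movie with overlaps, washouts and one division."""
    return simulate_colony(
        SimParams(seed=3, n_timepoints=14, n_mothers=2, overlap_bias=0.4, washout_prob=0.02)
    )


@pytest.fixture(scope="session")
def movie_spec(small_movie):
    frames = [f for f in small_movie.frames if f.masks]
    return optimize_size_boundaries(frames)


@pytest.fixture(scope="session")
def classifiers():
    """Tracking (A/B) and mother-bud classifiers trained on auxiliary movies."""
    return _train_default_classifiers(seed=5)
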