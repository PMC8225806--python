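import numpy as np
import pytest

from woundtexture.synthetic import SyntheticCohortConfig, TrajectoryParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_params():
    """Factory for generator parameters on small frames (fast tests)."""

    def make(**overrides):
        base = dict(
            frame_height=60,
            frame_width=80,
            pixels_per_cm=6.0,
            mean_wound_radius_cm=2.0,
        )
        base.update(overrides)
        return TrajectoryParams(**base)

    return make


@pytest.fixture
def small_cohort_config(fast_params):
    """A small but analysable synthetic cohort configuration."""
    return SyntheticCohortConfig(n_healed=5, n_unhealed=7, params=fast_params(), seed=7)
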