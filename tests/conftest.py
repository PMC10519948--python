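import numpy as np
import pytest

from circafeed.synth import (
    CohortSpec,
    alternans_profile,
    flat_profile,
    generate_hourly,
)


@pytest.fixture(scope="session")
def noise_free_spec():
    """Deterministic-mean conditions: no pen/pig offsets, no missing days."""
    return CohortSpec(
        n_days=28, missing_day_prob=0.0, sigma_pig=0.0, sigma_pen=0.0, seed=7
    )


@pytest.fixture(scope="session")
def alternans_series(noise_free_spec):
    return generate_hourly(alternans_profile(consistency=1.0), noise_free_spec)


@pytest.fixture(scope="session")
def flat_series(noise_free_spec):
    return generate_hourly(flat_profile(), noise_free_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
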