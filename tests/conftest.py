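import numpy as np
import pandas as pd
import pytest

from trflpdyn import (
    CommunityProfile,
    ProfileSeries,
    noise_free_scenario,
    simulate_campaign,
)


@pytest.fixture(scope="session")
def noise_free_campaign():
    """Env table, true profiles and rendered peaks for the clean preset."""
    return simulate_campaign(noise_free_scenario(seed=17))


@pytest.fixture()
def toy_peaks():
    """Hand-sized peak table spanning the size window boundaries."""
    rows = [
        ("s1", 0, 45.0, 100.0),
        ("s1", 0, 219.2, 700.0),
        ("s1", 0, 354.1, 150.0),
        ("s1", 0, 505.0, 80.0),
        ("s2", 15, 218.8, 400.0),
        ("s2", 15, 353.9, 500.0),
        ("s2", 15, 491.0, 100.0),
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "time_days", "fragment_length", "area"]
    )


def make_profile(sample_id, time_days, abund):
    return CommunityProfile(sample_id, time_days, dict(abund))


@pytest.fixture()
def three_sample_series():
    return ProfileSeries(
        [
            make_profile("a", 0, {219: 0.7, 354: 0.2, 491: 0.1}),
            make_profile("b", 15, {219: 0.5, 354: 0.4, 491: 0.1}),
            make_profile("c", 30, {219: 0.2, 354: 0.6, 491: 0.2}),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
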