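import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pelagicbarite as pb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ambient():
    """Ambient Lake Superior solution + thermodynamic preset."""
    return pb.load_preset()


@pytest.fixture()
def noiseless_truth():
    return pb.StationTruth(element_sigma=0.0, delta_sigma=0.0, seed=0)


@pytest.fixture()
def noiseless_profile(noiseless_truth):
    profile, _ = pb.generate_station(noiseless_truth)
    return profile


@pytest.fixture()
def noisy_profile():
    profile, _ = pb.generate_station(pb.StationTruth(seed=42))
    return profile
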