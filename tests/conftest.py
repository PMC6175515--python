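import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_params():
    from flushrisk import RiskModelParams

    return RiskModelParams()  # f_close=5, f_long=100, r_ref=125, linear


@pytest.fixture(scope="session")
def paper_like_dataset():
    """One study-sized synthetic dataset: 62 sandpipers + 38 phalaropes."""
    from flushrisk import generate_dataset, preset

    return generate_dataset(preset("paper_like"), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
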