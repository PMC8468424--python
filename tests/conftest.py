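import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from prstrat.panel import load_panel, weights_from_panel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def weights(panel):
    return weights_from_panel(panel)


@pytest.fixture(scope="session")
def panel_by_rsid(panel):
    return {rec.rsid: rec for rec in panel}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
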