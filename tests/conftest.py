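import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def edges64() -> np.ndarray:
    """Default histogram geometry: 64 bins spanning a 12.5 ns laser period."""
    return np.arange(65) * 12.5 / 64


@pytest.fixture(scope="session")
def centers64(edges64) -> np.ndarray:
    return 0.5 * (edges64[:-1] + edges64[1:])
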