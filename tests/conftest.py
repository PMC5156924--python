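import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """Two-phase, three-type observed table."""
    return pd.DataFrame(
        {"A": [30, 20], "B": [20, 25], "C": [0, 5]},
        index=pd.Index(["P1", "P2"], name="phase"),
    )
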