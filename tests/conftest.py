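import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20120220)


@pytest.fixture
def null_ma(rng):
    """Normalized MA table with i.i.d. standard-normal M and no A-trend."""
    n = 400
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "M": rng.normal(size=n),
            "A": rng.uniform(6, 13, size=n),
            "normalized": True,
        }
    )
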