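import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_setts(coords, site_id="X", sett_type=None, occupied=None, reproduction=None,
               perp=None):
    """Small sett-record frame from coordinate pairs (defaults: occupied secondary)."""
    n = len(coords)
    return pd.DataFrame({
        "sett_id": [f"{site_id}-S{i + 1:03d}" for i in range(n)],
        "site_id": site_id,
        "x_m": [c[0] for c in coords],
        "y_m": [c[1] for c in coords],
        "sett_type": sett_type if sett_type is not None else ["secondary"] * n,
        "occupied": occupied if occupied is not None else [True] * n,
        "reproduction": reproduction if reproduction is not None else [False] * n,
        "perp_distance_m": perp if perp is not None else [np.nan] * n,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
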