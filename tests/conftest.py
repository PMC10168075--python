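import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from innerbark.timeseries_io import Flag, GriddedSeries, SAMPLES_PER_DAY


def make_series(values, start="2019-08-01", unit="µm", flags=None):
    """Gridded series helper on the canonical 10-min grid."""
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start, periods=len(values), freq="600s")
    if flags is None:
        flags = np.where(np.isfinite(values), Flag.OK, Flag.MISSING).astype(np.int8)
    return GriddedSeries(ts, values, flags, unit)


@pytest.fixture(scope="session")
def tiny_campaign():
    from innerbark.synthetic_data import simulate_campaign

    return simulate_campaign("tiny", seed=11)


@pytest.fixture(scope="session")
def field_campaign():
    from innerbark.synthetic_data import simulate_campaign

    return simulate_campaign("paper_scale", seed=5)
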