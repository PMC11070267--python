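import datetime as dt
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dielflux.io_core import RunConfig, SiteConfig
from dielflux.synthetic import SimParams, simulate_site


@pytest.fixture(scope="session")
def midlat_site():
    return SiteConfig("ch1", "Midlat", 47.0, 8.0, 500.0)


@pytest.fixture(scope="session")
def helsinki_site():
    return SiteConfig("hel", "Helsinki", 60.17, 24.94, 10.0)


@pytest.fixture(scope="session")
def june_config():
    return RunConfig(period=(dt.date(2021, 6, 1), dt.date(2021, 6, 10)))


@pytest.fixture(scope="session")
def june_sim(midlat_site):
    """Ten simulated June days at a mid-latitude site, with ground truth."""
    params = SimParams(seed=42, start_date=dt.date(2021, 6, 1), end_date=dt.date(2021, 6, 10))
    echoes, intervals, truth = simulate_site(midlat_site, params)
    return {"params": params, "echoes": echoes, "intervals": intervals, "truth": truth}
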