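"""Shared study configuration for the numbered analysis scripts.

The study network is a 14-site transect along the European latitude range a
vertical-looking radar network covers (43.5-59.1 deg N), simulated over six
weeks bracketing September so every site has nautical night.  All scripts
read and write below results/.
"""

import datetime as dt
from pathlib import Path

from dielflux.io_core import RunConfig, SiteConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
OUT = RESULTS / "pipeline"

PERIOD = (dt.date(2021, 8, 20), dt.date(2021, 9, 30))

SITES = [
    SiteConfig(f"s{i:02d}", f"Site {i}", 43.5 + 1.2 * i, -1.5 + 1.8 * i, 50.0 + 30.0 * i)
    for i in range(14)
]


def run_config(seed: int) -> RunConfig:
    return RunConfig(period=PERIOD, seed=seed)
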