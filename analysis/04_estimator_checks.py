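"""Check the traffic-rate estimator against the generator's ground truth.

Merges the pipeline's phase aggregates with the integrated truth stored by
the simulator and reports the relative error of recovered daily phase totals
(interior days with full monitoring).  Writes
results/pipeline/recovery_check.csv.
"""

import numpy as np
import pandas as pd

from _common import DATA, OUT, PERIOD


def main() -> None:
    agg = pd.read_csv(OUT / "phase_agg.csv")
    truth = pd.read_csv(DATA / "truth.csv")
    m = agg.merge(truth, on=["site_id", "anchor_date", "phase"])
    interior = (m["anchor_date"] > PERIOD[0].isoformat()) & (
        m["anchor_date"] < PERIOD[1].isoformat()
    )
    m = m[interior].dropna(subset=["total_traffic", "true_total_traffic"])
    m = m[m["true_total_traffic"] > 1.0]
    m["rel_err"] = (m["total_traffic"] - m["true_total_traffic"]) / m["true_total_traffic"]

    by_phase = m.groupby("phase")["rel_err"].agg(["mean", "std", "count"])
    m[["site_id", "anchor_date", "phase", "total_traffic", "true_total_traffic", "rel_err"]].to_csv(
        OUT / "recovery_check.csv", index=False
    )
    print(f"{len(m)} phase totals compared against integrated truth")
    print(f"overall mean relative error: {m['rel_err'].mean():+.4f}")
    print(by_phase.to_string(float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
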