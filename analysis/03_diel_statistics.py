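"""Summarize the beta-ANOVA comparisons across sites.

Reads the pipeline outputs and reports, per measure and diel phase, the
omnibus likelihood-ratio p-value, the number and share of Holm-significant
pairwise site differences, and the largest pairwise effect size (absolute
difference of fitted mean proportions).  Writes
results/pipeline/stats_summary.csv.
"""

import pandas as pd

from _common import OUT


def main() -> None:
    omnibus = pd.read_csv(OUT / "omnibus.csv")
    posthoc = pd.read_csv(OUT / "posthoc.csv")

    rows = []
    for (measure, phase), grp in posthoc.groupby(["measure", "phase"]):
        om = omnibus[(omnibus["measure"] == measure) & (omnibus["phase"] == phase)]
        rows.append(
            {
                "measure": measure,
                "phase": phase,
                "omnibus_p": float(om["p"].iloc[0]) if len(om) else float("nan"),
                "n_pairs": len(grp),
                "n_significant": int(grp["significant"].sum()),
                "share_significant": float(grp["significant"].mean()),
                "max_abs_effect": float(grp["effect_size"].abs().max()),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "stats_summary.csv", index=False)

    total = len(posthoc)
    sig = int(posthoc["significant"].sum())
    print(f"{sig} of {total} pairwise site comparisons significant after Holm "
          f"({100 * sig / total:.1f}%)")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
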