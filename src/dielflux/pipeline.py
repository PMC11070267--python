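"""End-to-end pipeline: echoes in, statistics and summary tables out.

Stages: insect/band filter -> diel-phase segmentation -> hourly MTR ->
phase aggregates -> daily proportions -> boundary compression -> beta-ANOVA
omnibus and Holm-corrected pairwise post-hoc tests per diel phase and
measure -> monthly summaries and heatmap matrices.  Every stage lives in its
own module; this driver only wires them together, applies the site-exclusion
list before any statistics, and writes the CSV outputs plus a
machine-readable run log.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dielflux import io_core, stats, summaries, traffic
from dielflux.io_core import RunConfig, SiteConfig
from dielflux.solar import PHASES, diel_phase_table, phases_to_frame
from dielflux.stats import posthoc_table

__all__ = ["run_pipeline", "phase_statistics"]


def phase_statistics(
    daily_props: pd.DataFrame,
    exclude_sites: Sequence[str] = (),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus and pairwise beta-ANOVA per measure and diel phase.

    Site exclusion is applied first; compression uses N = the number of
    day-values entering that phase's model.  Sites with fewer than two
    complete days in a phase are dropped from that phase's comparisons.
    Returns (omnibus table, posthoc table).
    """
    props = daily_props[daily_props["complete"]]
    props = props[~props["site_id"].isin(set(exclude_sites))]
    omni_rows, post_frames = [], []
    for measure, col in (("intensity", "prop_intensity"), ("traffic", "prop_traffic")):
        for phase in PHASES:
            sel = props[props["phase"] == phase].dropna(subset=[col])
            counts = sel.groupby("site_id").size()
            keep = counts[counts >= 2].index
            sel = sel[sel["site_id"].isin(keep)]
            if sel["site_id"].nunique() < 2:
                continue
            y = stats.compress_proportion(sel[col].to_numpy(float), len(sel))
            labels = sel["site_id"].to_numpy()
            omni = stats.omnibus_test(y, labels)
            omni_rows.append(
                {
                    "measure": measure,
                    "phase": phase,
                    "statistic": omni["statistic"],
                    "df": omni["df"],
                    "p": omni["p"],
                }
            )
            results = stats.pairwise_posthoc(y, labels, alpha=alpha, phase=phase)
            post_frames.append(posthoc_table(results, measure))
    omnibus = pd.DataFrame(omni_rows, columns=["measure", "phase", "statistic", "df", "p"])
    posthoc = (
        pd.concat(post_frames, ignore_index=True)
        if post_frames
        else pd.DataFrame(
            columns=["measure", "phase", "site_a", "site_b", "effect_size", "p_raw", "p_holm", "significant"]
        )
    )
    return omnibus, posthoc


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    exclude_sites: Sequence[str] = (),
) -> dict:
    """Run the full analysis on a directory of input CSVs.

    ``in_dir`` must contain sites.csv, echoes.csv and intervals.csv (the
    interchange schemas of :mod:`dielflux.io_core`).  All output tables plus
    run_log.json are written to ``out_dir``; the frames are also returned.
    Any stage failure aborts with the stage name and cause.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()

    stage = "read_inputs"
    try:
        sites = io_core.read_sites(in_dir / "sites.csv")
        echoes = io_core.read_echo_frame(in_dir / "echoes.csv")
        intervals = io_core.read_intervals(in_dir / "intervals.csv")

        stage = "filter_insects"
        insects = traffic.filter_insects(echoes, config)

        stage = "diel_phases"
        phase_ivs = []
        for site in sites:
            phase_ivs.extend(
                diel_phase_table(site, config.period[0], config.period[1], config)
            )
        phases_df = phases_to_frame(phase_ivs)

        stage = "hourly_mtr"
        hourly = pd.concat(
            [traffic.hourly_mtr(insects, intervals, site, config) for site in sites],
            ignore_index=True,
        )

        stage = "phase_aggregates"
        agg = traffic.phase_aggregates(insects, phase_ivs, intervals, config)

        stage = "daily_proportions"
        props = stats.daily_proportions(agg)

        stage = "statistics"
        omnibus, posthoc = phase_statistics(props, exclude_sites=exclude_sites)

        stage = "monthly_summary"
        monthly = summaries.monthly_phase_summary(props, insects, phase_ivs)

        stage = "heatmaps"
        heatmaps = {}
        for site in sites:
            h = hourly[hourly["site_id"] == site.site_id]
            heatmaps[site.site_id] = (
                summaries.hourly_mtr_matrix(h),
                summaries.hourly_proportion_matrix(h),
            )

        stage = "write_outputs"
        phases_out = phases_df.copy()
        for col in ("start_utc", "end_utc"):
            phases_out[col] = phases_out[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
        phases_out.to_csv(out_dir / "phases.csv", index=False)
        hourly_out = hourly.copy()
        hourly_out["hour_start_utc"] = hourly_out["hour_start_utc"].dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
        hourly_out.to_csv(out_dir / "hourly_mtr.csv", index=False)
        agg.to_csv(out_dir / "phase_agg.csv", index=False)
        props.to_csv(out_dir / "daily_props.csv", index=False)
        omnibus.to_csv(out_dir / "omnibus.csv", index=False)
        posthoc.to_csv(out_dir / "posthoc.csv", index=False)
        monthly.to_csv(out_dir / "monthly_summary.csv", index=False)
        for sid, (m, p) in heatmaps.items():
            m.to_csv(out_dir / f"heatmap_mtr_{sid}.csv")
            p.to_csv(out_dir / f"heatmap_prop_{sid}.csv")

        log = {
            "config": {
                "altitude_band": list(config.altitude_band),
                "p_insect_min": config.p_insect_min,
                "min_monitoring_fraction": config.min_monitoring_fraction,
                "twilight_threshold_deg": config.twilight_threshold_deg,
                "period": [d.isoformat() for d in config.period],
                "seed": config.seed,
            },
            "excluded_sites": list(exclude_sites),
            "n_sites": len(sites),
            "n_echoes_in": int(len(echoes)),
            "n_insect_echoes": int(len(insects)),
            "n_phase_intervals": int(len(phase_ivs)),
            "n_hour_bins": int(len(hourly)),
            "n_complete_days": int(
                props[props["complete"]].groupby(["site_id", "anchor_date"]).ngroups
            ),
            "n_posthoc_tests": int(len(posthoc)),
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "sites": sites,
        "echoes": echoes,
        "insects": insects,
        "phases": phases_df,
        "phase_intervals": phase_ivs,
        "hourly": hourly,
        "phase_agg": agg,
        "daily_props": props,
        "omnibus": omnibus,
        "posthoc": posthoc,
        "monthly": monthly,
        "heatmaps": heatmaps,
        "run_log": log,
    }
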