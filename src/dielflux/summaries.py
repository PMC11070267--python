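"""Heatmap matrices and monthly per-phase summaries.

Heatmaps are date x UTC-clock-hour matrices of hourly MTR or of daily
proportional hourly traffic (each day's non-missing hourly rates divided by
that day's total, so a row sums to 1 whenever the day saw any traffic).
Missing bins (NaN) are distinguished from true zeros.

Monthly summaries report, per site, month and diel phase: the arithmetic
mean of the daily proportional intensity and traffic, the relative mean
radar cross section (a phase's mean RCSmax divided by the sum of the phase
means, summing to 1 across phases), and the mean over days of the daily
median flight altitude of phase-assigned insect echoes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from dielflux.solar import PHASES, DielPhaseInterval, assign_phase_bulk

__all__ = ["hourly_mtr_matrix", "hourly_proportion_matrix", "monthly_phase_summary"]


def hourly_mtr_matrix(hourly: pd.DataFrame) -> pd.DataFrame:
    """Date x 24-hour matrix of MTR for one site (NaN = missing)."""
    df = hourly.copy()
    ts = pd.to_datetime(df["hour_start_utc"], utc=True)
    df["date"] = ts.dt.date
    df["hour"] = ts.dt.hour
    return df.pivot_table(index="date", columns="hour", values="mtr", dropna=False)


def hourly_proportion_matrix(hourly: pd.DataFrame) -> pd.DataFrame:
    """Daily proportional hourly traffic: each value in [0, 1] says how much
    of that day's insect traffic occurred in that clock hour.

    Non-missing hours are divided by the day's sum; an all-zero day stays
    all zeros (distinct from an all-missing day, which stays NaN).
    """
    mat = hourly_mtr_matrix(hourly)
    vals = mat.to_numpy(float)
    sums = np.nansum(vals, axis=1, keepdims=True)
    all_missing = np.isnan(vals).all(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sums > 0, vals / sums, np.where(np.isnan(vals), np.nan, 0.0))
    out = np.where(all_missing, np.nan, out)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def monthly_phase_summary(
    daily_props: pd.DataFrame,
    echoes: pd.DataFrame,
    phase_intervals: Sequence[DielPhaseInterval],
) -> pd.DataFrame:
    """Monthly means per site and diel phase.

    ``echoes`` must already be insect/band filtered; they are assigned to
    phases by exact interval lookup.  RCS shares are only defined for
    site-months in which every geometrically occurring phase also has echo
    data *and* all four phases occur; months with an absent phase (no-night
    high-latitude months) get NaN shares rather than renormalized ones.
    """
    props = daily_props[daily_props["complete"]].copy()
    props["month"] = props["anchor_date"].astype(str).str.slice(0, 7)
    prop_agg = (
        props.groupby(["site_id", "month", "phase"])
        .agg(
            mean_prop_intensity=("prop_intensity", "mean"),
            mean_prop_traffic=("prop_traffic", "mean"),
            n_days=("prop_intensity", "size"),
        )
        .reset_index()
    )

    # phase-assign echoes per site
    echo_rows = []
    by_site: dict[str, list[DielPhaseInterval]] = {}
    for p in phase_intervals:
        by_site.setdefault(p.site_id, []).append(p)
    for sid, ivs in by_site.items():
        sel = echoes[echoes["site_id"] == sid]
        if len(sel) == 0:
            continue
        t = pd.to_datetime(sel["timestamp_utc"], utc=True).astype("int64").to_numpy() / 1e9
        labels, idx = assign_phase_bulk(t, ivs)
        ivs_sorted = sorted(ivs, key=lambda p: p.start)
        anchors = np.array([p.anchor_date.isoformat() for p in ivs_sorted] + [""])
        ok = idx >= 0
        echo_rows.append(
            pd.DataFrame(
                {
                    "site_id": sid,
                    "phase": labels[ok],
                    "month": np.array([a[:7] for a in anchors[idx[ok]]]),
                    "rcs": sel["rcs_max_cm2"].to_numpy(float)[ok],
                    "alt": sel["altitude_agl_m"].to_numpy(float)[ok],
                    "anchor_date": anchors[idx[ok]],
                }
            )
        )
    if echo_rows:
        ech = pd.concat(echo_rows, ignore_index=True)
        rcs_mean = (
            ech.groupby(["site_id", "month", "phase"])["rcs"].mean().rename("mean_rcs")
        )
        daily_med = (
            ech.groupby(["site_id", "month", "phase", "anchor_date"])["alt"]
            .median()
            .rename("daily_median_alt")
            .reset_index()
        )
        alt_mean = (
            daily_med.groupby(["site_id", "month", "phase"])["daily_median_alt"]
            .mean()
            .rename("mean_daily_median_alt_m")
        )
        extra = pd.concat([rcs_mean, alt_mean], axis=1).reset_index()
    else:
        extra = pd.DataFrame(
            columns=["site_id", "month", "phase", "mean_rcs", "mean_daily_median_alt_m"]
        )

    out = prop_agg.merge(extra, on=["site_id", "month", "phase"], how="outer")

    # relative RCS shares: require all four phases with data in the cell
    shares = []
    for (sid, month), grp in out.groupby(["site_id", "month"]):
        vals = grp.set_index("phase")["mean_rcs"]
        if set(PHASES) <= set(vals.index) and vals.reindex(PHASES).notna().all():
            total = vals.reindex(list(PHASES)).sum()
            share = vals / total
        else:
            share = vals * np.nan
        for phase, v in share.items():
            shares.append({"site_id": sid, "month": month, "phase": phase, "rel_rcs": v})
    out = out.merge(pd.DataFrame(shares), on=["site_id", "month", "phase"], how="left")
    cols = [
        "site_id",
        "month",
        "phase",
        "mean_prop_intensity",
        "mean_prop_traffic",
        "rel_rcs",
        "mean_daily_median_alt_m",
        "n_days",
    ]
    return out.reindex(columns=cols).sort_values(["site_id", "month", "phase"]).reset_index(drop=True)
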