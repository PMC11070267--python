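"""Domain types, validation and delimited-text I/O for the radar pipeline.

All timestamps are UTC (tz-aware pandas Timestamps in frames, ISO-8601 in
files); local solar time enters the analysis only through site longitude in
the solar module.  CSV (RFC-4180, "." decimal) is the interchange format for
echoes, site lists, protocol/rain intervals and all downstream outputs; one
file may hold several sites.

Echo altitudes are metres above the radar (AGL relative to the antenna), not
above sea level.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SiteConfig",
    "EchoRecord",
    "RunConfig",
    "ECHO_COLUMNS",
    "SITE_COLUMNS",
    "INTERVAL_COLUMNS",
    "read_echo_table",
    "write_echo_table",
    "read_echo_frame",
    "write_echo_frame",
    "read_sites",
    "write_sites",
    "read_intervals",
    "write_intervals",
    "merge_intervals",
    "merge_spans",
    "spans_overlap_seconds",
    "clip_spans",
    "validate_network",
]

ECHO_COLUMNS = [
    "site_id",
    "timestamp_utc",
    "altitude_agl_m",
    "p_insect",
    "p_bird",
    "p_nonbio",
    "rcs_max_cm2",
]
SITE_COLUMNS = ["site_id", "name", "lat_deg", "lon_deg", "elev_m"]
INTERVAL_COLUMNS = ["site_id", "kind", "start_utc", "end_utc"]
INTERVAL_KINDS = ("protocol_shortpulse", "rain")

_PROB_EPS = 1e-6


@dataclass(frozen=True)
class SiteConfig:
    """One radar site: identifier, location and antenna elevation (m a.s.l.)."""

    site_id: str
    name: str
    latitude: float
    longitude: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class EchoRecord:
    """One classified radar detection.

    ``p_insect`` plus the non-insect class probabilities in ``p_other`` must
    not exceed 1 (within epsilon); ``rcs_max`` is the low-pass-filtered
    maximum radar cross section in cm^2, a proxy for body mass.
    """

    site_id: str
    timestamp: pd.Timestamp
    altitude_agl: float
    p_insect: float
    p_other: Mapping[str, float] = field(default_factory=dict)
    rcs_max: float = 1.0
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError("EchoRecord timestamp must be timezone-aware UTC")
        if self.altitude_agl < 0:
            raise ValueError(f"altitude_agl {self.altitude_agl} < 0")
        if not 0.0 <= self.p_insect <= 1.0:
            raise ValueError(f"p_insect {self.p_insect} outside [0, 1]")
        for k, v in self.p_other.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p_other[{k}] = {v} outside [0, 1]")
        if self.p_insect + sum(self.p_other.values()) > 1.0 + _PROB_EPS:
            raise ValueError("class probabilities sum to more than 1")
        if self.rcs_max <= 0:
            raise ValueError(f"rcs_max {self.rcs_max} must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with the protocol's default filtering rules.

    altitude_band
        Analysis band in metres above the radar, default 50-500 m.
    p_insect_min
        Minimum insect class probability (echo is kept only when p_insect
        exceeds this AND every other class probability), default 0.4.
    min_monitoring_fraction
        Minimum effective monitoring fraction of a time bin below which its
        traffic rate is treated as missing, default 0.2 (12 min of an hour).
    twilight_threshold_deg
        Solar elevation of nautical dawn/dusk, default -12 deg.
    period
        Inclusive [start, end] calendar dates of the analysis (UTC).
    """

    altitude_band: tuple[float, float] = (50.0, 500.0)
    p_insect_min: float = 0.4
    min_monitoring_fraction: float = 0.2
    twilight_threshold_deg: float = -12.0
    period: tuple[_dt.date, _dt.date] = (_dt.date(2021, 3, 1), _dt.date(2021, 10, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.altitude_band
        if not lo < hi:
            raise ValueError("altitude band min must be < max")
        if not 0.0 <= self.min_monitoring_fraction <= 1.0:
            raise ValueError("min_monitoring_fraction outside [0, 1]")
        if self.period[0] > self.period[1]:
            raise ValueError("period start after period end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "altitude_band" in raw:
            kwargs["altitude_band"] = tuple(float(x) for x in raw["altitude_band"])
        for key in ("p_insect_min", "min_monitoring_fraction", "twilight_threshold_deg"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "period" in raw:
            kwargs["period"] = tuple(
                _dt.date.fromisoformat(str(d)) for d in raw["period"]
            )
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "altitude_band": list(self.altitude_band),
            "p_insect_min": self.p_insect_min,
            "min_monitoring_fraction": self.min_monitoring_fraction,
            "twilight_threshold_deg": self.twilight_threshold_deg,
            "period": [d.isoformat() for d in self.period],
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# echo tables


def _parse_utc(series: pd.Series, *, context: str) -> pd.Series:
    out = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    if out.isna().any():
        bad = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ValueError(f"{context}: unparseable timestamp on data line {bad + 1}")
    return out


def read_echo_frame(path: str | Path) -> pd.DataFrame:
    """Read an echo CSV into a validated frame (row order preserved)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in ECHO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["timestamp_utc"] = _parse_utc(df["timestamp_utc"], context=str(path))
    for col, lo, hi in [
        ("p_insect", 0.0, 1.0),
        ("p_bird", 0.0, 1.0),
        ("p_nonbio", 0.0, 1.0),
    ]:
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero((vals < lo) | (vals > hi) | np.isnan(vals))
        if bad.size:
            raise ValueError(
                f"{path}: {col} = {vals[bad[0]]} outside [{lo}, {hi}] on data line "
                f"{int(bad[0]) + 1}"
            )
    alt = df["altitude_agl_m"].to_numpy(dtype=float)
    bad = np.flatnonzero((alt < 0) | np.isnan(alt))
    if bad.size:
        raise ValueError(f"{path}: negative altitude on data line {int(bad[0]) + 1}")
    rcs = df["rcs_max_cm2"].to_numpy(dtype=float)
    bad = np.flatnonzero((rcs <= 0) | np.isnan(rcs))
    if bad.size:
        raise ValueError(f"{path}: non-positive rcs_max on data line {int(bad[0]) + 1}")
    psum = (
        df["p_insect"].to_numpy(float)
        + df["p_bird"].to_numpy(float)
        + df["p_nonbio"].to_numpy(float)
    )
    bad = np.flatnonzero(psum > 1.0 + _PROB_EPS)
    if bad.size:
        raise ValueError(
            f"{path}: class probabilities sum to {psum[bad[0]]:.6f} > 1 on data line "
            f"{int(bad[0]) + 1}"
        )
    return df


def write_echo_frame(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    cols = [c for c in ECHO_COLUMNS if c in out.columns] + [
        c for c in out.columns if c not in ECHO_COLUMNS
    ]
    out[cols].to_csv(path, index=False)


def _frame_to_records(df: pd.DataFrame) -> list[EchoRecord]:
    records = []
    has_truth = "truth_label" in df.columns
    for row in df.itertuples(index=False):
        records.append(
            EchoRecord(
                site_id=row.site_id,
                timestamp=row.timestamp_utc,
                altitude_agl=float(row.altitude_agl_m),
                p_insect=float(row.p_insect),
                p_other={"bird": float(row.p_bird), "nonbio": float(row.p_nonbio)},
                rcs_max=float(row.rcs_max_cm2),
                truth_label=(str(row.truth_label) if has_truth else None),
            )
        )
    return records


def records_to_frame(records: Sequence[EchoRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "site_id": r.site_id,
                "timestamp_utc": r.timestamp,
                "altitude_agl_m": r.altitude_agl,
                "p_insect": r.p_insect,
                "p_bird": r.p_other.get("bird", 0.0),
                "p_nonbio": r.p_other.get("nonbio", 0.0),
                "rcs_max_cm2": r.rcs_max,
            }
        )
    df = pd.DataFrame(rows, columns=ECHO_COLUMNS)
    if any(r.truth_label is not None for r in records):
        df["truth_label"] = [r.truth_label for r in records]
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], utc=True)
    return df


def read_echo_table(path: str | Path) -> list[EchoRecord]:
    """Read an echo CSV into a list of :class:`EchoRecord` (row order kept)."""
    return _frame_to_records(read_echo_frame(path))


def write_echo_table(records: Sequence[EchoRecord], path: str | Path) -> None:
    write_echo_frame(records_to_frame(records), path)


# ---------------------------------------------------------------------------
# sites


def read_sites(path: str | Path) -> list[SiteConfig]:
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    sites = [
        SiteConfig(
            site_id=row.site_id,
            name=str(row.name_),
            latitude=float(row.lat_deg),
            longitude=float(row.lon_deg),
            elevation=float(row.elev_m),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate site_id")
    return sites


def write_sites(sites: Sequence[SiteConfig], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "name": s.name,
                "lat_deg": s.latitude,
                "lon_deg": s.longitude,
                "elev_m": s.elevation,
            }
            for s in sites
        ],
        columns=SITE_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interval tables and span arithmetic

# Spans are float (N, 2) arrays of [start, end) epoch seconds; merged spans
# are sorted, non-overlapping and non-abutting.


def merge_spans(spans: np.ndarray) -> np.ndarray:
    """Union of half-open spans; overlapping or abutting spans are merged."""
    spans = np.asarray(spans, dtype=float).reshape(-1, 2)
    if spans.size == 0:
        return spans
    order = np.argsort(spans[:, 0], kind="stable")
    spans = spans[order]
    merged = [spans[0].copy()]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.array(merged)


def spans_overlap_seconds(spans: np.ndarray, start: float, end: float) -> float:
    """Total seconds of overlap between merged ``spans`` and [start, end)."""
    if len(spans) == 0 or end <= start:
        return 0.0
    lo = np.maximum(spans[:, 0], start)
    hi = np.minimum(spans[:, 1], end)
    return float(np.clip(hi - lo, 0.0, None).sum())


def clip_spans(spans: np.ndarray, start: float, end: float) -> np.ndarray:
    """Merged spans intersected with [start, end)."""
    if len(spans) == 0:
        return np.empty((0, 2))
    lo = np.maximum(spans[:, 0], start)
    hi = np.minimum(spans[:, 1], end)
    keep = hi > lo
    return np.column_stack([lo[keep], hi[keep]])


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read and normalize an interval table.

    Per site and kind, overlapping or abutting intervals are merged, so the
    returned covered duration equals the union of the input rows.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "kind": str})
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["start_utc"] = _parse_utc(df["start_utc"], context=str(path))
    df["end_utc"] = _parse_utc(df["end_utc"], context=str(path))
    bad = np.flatnonzero((df["end_utc"] <= df["start_utc"]).to_numpy())
    if bad.size:
        raise ValueError(f"{path}: end <= start on data line {int(bad[0]) + 1}")
    return merge_intervals(df)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting intervals per (site_id, kind); idempotent."""
    if len(df) == 0:
        return df.copy()
    rows = []
    for (site, kind), grp in df.groupby(["site_id", "kind"], sort=True):
        spans = np.column_stack(
            [
                grp["start_utc"].astype("int64").to_numpy() / 1e9,
                grp["end_utc"].astype("int64").to_numpy() / 1e9,
            ]
        )
        for s, e in merge_spans(spans):
            rows.append(
                {
                    "site_id": site,
                    "kind": kind,
                    "start_utc": pd.Timestamp(s, unit="s", tz="UTC"),
                    "end_utc": pd.Timestamp(e, unit="s", tz="UTC"),
                }
            )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_intervals(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("start_utc", "end_utc"):
        out[col] = pd.to_datetime(out[col], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[INTERVAL_COLUMNS].to_csv(path, index=False)


def site_spans(intervals: pd.DataFrame, site_id: str, kind: str) -> np.ndarray:
    """Merged [start, end) epoch-second spans for one site and interval kind."""
    sel = intervals[(intervals["site_id"] == site_id) & (intervals["kind"] == kind)]
    if len(sel) == 0:
        return np.empty((0, 2))
    spans = np.column_stack(
        [
            sel["start_utc"].astype("int64").to_numpy() / 1e9,
            sel["end_utc"].astype("int64").to_numpy() / 1e9,
        ]
    )
    return merge_spans(spans)


# ---------------------------------------------------------------------------
# network validation


def validate_network(
    sites: Sequence[SiteConfig],
    echoes: pd.DataFrame,
    intervals: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Report-only consistency check of a loaded network.

    Returns a dict with ``issues`` (list of strings), plus summary fractions:
    echoes with unknown site, echoes outside the configured period, and the
    fraction outside the altitude band.
    """
    issues: list[str] = []
    known = {s.site_id for s in sites}
    n = len(echoes)

    unknown_echo = ~echoes["site_id"].isin(known) if n else pd.Series(dtype=bool)
    for sid in sorted(set(echoes.loc[unknown_echo, "site_id"])) if n else []:
        issues.append(f"echoes reference unknown site_id '{sid}'")
    for sid in sorted(set(intervals["site_id"]) - known):
        issues.append(f"intervals reference unknown site_id '{sid}'")

    if n:
        ts = pd.to_datetime(echoes["timestamp_utc"], utc=True)
        start = pd.Timestamp(config.period[0], tz="UTC")
        end = pd.Timestamp(config.period[1], tz="UTC") + pd.Timedelta(days=1)
        outside_period = ((ts < start) | (ts >= end)).mean()
        lo, hi = config.altitude_band
        alt = echoes["altitude_agl_m"].to_numpy(float)
        outside_band = float(((alt < lo) | (alt > hi)).mean())
        if outside_period > 0:
            issues.append(
                f"{outside_period:.1%} of echoes outside configured period"
            )
    else:
        outside_period = 0.0
        outside_band = 0.0

    return {
        "issues": issues,
        "n_echoes": n,
        "frac_unknown_site": float(unknown_echo.mean()) if n else 0.0,
        "frac_outside_period": float(outside_period),
        "frac_outside_band": outside_band,
    }
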