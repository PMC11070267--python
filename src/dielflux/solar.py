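"""Solar geometry and diel-phase segmentation.

The four diel phases are bounded by the *geometric* centre of the sun (no
refraction correction): crepuscular morning runs from nautical dawn (sun
centre at -12 deg, rising) to sunrise (0 deg), day from sunrise to sunset,
crepuscular evening from sunset to nautical dusk (-12 deg, setting) and night
from nautical dusk to the next nautical dawn.  A *diel day* is anchored at
nautical dawn and runs to the next nautical dawn, so the night interval is
contiguous and belongs to the anchor date of the dawn that opens it.

At high latitudes around the summer solstice the sun may stay above -12 deg
all night ("no nautical night").  The whole sunset-to-next-sunrise span is
then twilight; its first half (by clock time) is assigned to crepuscular
evening and its second half to crepuscular morning, and no night interval is
emitted.  The diel-day boundary in that case is the twilight midpoint.

Solar position uses a low-accuracy NOAA/Meeus-class ephemeris (geometric
elevation accurate to ~0.01-0.1 deg over 1950-2100), ample for phase bins
tens of minutes long; event times are refined to well under a second against
this ephemeris by bracketed root finding.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from dielflux.io_core import RunConfig, SiteConfig

__all__ = [
    "SolarEvents",
    "DielPhaseInterval",
    "PHASES",
    "solar_elevation",
    "crossing_times",
    "solar_events",
    "diel_phases",
    "diel_phase_table",
    "assign_phase",
    "phases_to_frame",
]

PHASES = ("crepuscular_morning", "day", "crepuscular_evening", "night")

_EPOCH_1950 = -631152000.0
_EPOCH_2100 = 4102444800.0
_DEG = np.pi / 180.0


def _to_epoch(ts) -> np.ndarray | float:
    """Coerce timestamps (Timestamp/datetime/ISO str/epoch s/arrays) to epoch s."""
    if isinstance(ts, (int, float, np.floating, np.integer)):
        return float(ts)
    if isinstance(ts, str):
        return pd.Timestamp(ts, tz="UTC").timestamp()
    if isinstance(ts, pd.Timestamp):
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        return ts.timestamp()
    if isinstance(ts, _dt.datetime):
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=_dt.timezone.utc)
        return ts.timestamp()
    arr = np.asarray(ts)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[ns]").astype("int64") / 1e9
    return arr.astype(float)


def _declination_eqtime(epoch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solar declination (deg) and equation of time (minutes)."""
    jd = epoch / 86400.0 + 2440587.5
    T = (jd - 2451545.0) / 36525.0

    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)

    Mr = M * _DEG
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = (125.04 - 1934.136 * T) * _DEG
    lam = (true_long - 0.00569 - 0.00478 * np.sin(omega)) * _DEG

    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = (eps0 + 0.00256 * np.cos(omega)) * _DEG

    decl = np.arcsin(np.sin(eps) * np.sin(lam)) / _DEG

    y = np.tan(eps / 2.0) ** 2
    L0r = L0 * _DEG
    eqtime = 4.0 / _DEG * (
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )
    return decl, eqtime


def solar_elevation(lat: float, lon: float, timestamp) -> np.ndarray | float:
    """Geometric (unrefracted) solar elevation in degrees.

    Parameters
    ----------
    lat, lon : decimal degrees (east positive).
    timestamp : UTC instant(s) — epoch seconds, Timestamp, datetime, ISO
        string or array thereof; years 1950–2100.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    epoch = np.asarray(_to_epoch(timestamp), dtype=float)
    if epoch.size and (epoch.min() < _EPOCH_1950 or epoch.max() > _EPOCH_2100):
        raise ValueError("timestamp outside supported range 1950-2100")
    decl, eqtime = _declination_eqtime(epoch)

    minutes_utc = np.mod(epoch, 86400.0) / 60.0
    tst = np.mod(minutes_utc + eqtime + 4.0 * lon, 1440.0)
    ha = (tst / 4.0 - 180.0) * _DEG

    latr = lat * _DEG
    declr = decl * _DEG
    sin_el = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(ha)
    el = np.arcsin(np.clip(sin_el, -1.0, 1.0)) / _DEG
    if np.isscalar(timestamp) or isinstance(timestamp, (pd.Timestamp, _dt.datetime, str, float, int)):
        return float(el)
    return el


# ---------------------------------------------------------------------------
# event solving


def _elev_fn(site: SiteConfig):
    return lambda t: solar_elevation(site.latitude, site.longitude, t)


def _refine_extremum(site: SiteConfig, t_guess: float, sign: float) -> float:
    """Refine a grid extremum of elevation; sign=+1 for max, -1 for min."""
    f = _elev_fn(site)
    res = minimize_scalar(
        lambda t: -sign * f(t),
        bounds=(t_guess - 180.0, t_guess + 180.0),
        method="bounded",
        options={"xatol": 0.01},
    )
    return float(res.x)


def _grid_crossings(
    site: SiteConfig, t0: float, t1: float, threshold: float, step: float = 60.0
) -> tuple[list[float], list[float]]:
    """All up/down crossings of ``threshold`` in [t0, t1], refined by brentq."""
    grid = np.arange(t0, t1 + step, step)
    el = solar_elevation(site.latitude, site.longitude, grid) - threshold
    f = lambda t: solar_elevation(site.latitude, site.longitude, t) - threshold
    ups, downs = [], []
    sign = np.sign(el)
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    for i in idx:
        t = brentq(f, grid[i], grid[i + 1], xtol=1e-4)
        (ups if el[i] < 0 else downs).append(float(t))
    # exact-zero grid points (measure zero, but keep brentq happy)
    for i in np.flatnonzero(sign == 0):
        t = float(grid[i])
        if 0 < i < len(grid) - 1:
            (ups if el[i - 1] < 0 else downs).append(t)
    return ups, downs


@dataclass(frozen=True)
class SolarEvents:
    """Solar threshold events for one site and anchor date (UTC).

    Event attributes are epoch-second floats or ``None`` when the crossing
    does not occur that diel day.  ``noon``/``prev_midnight``/``next_midnight``
    are the solar culminations bracketing the local day.
    """

    site_id: str
    anchor_date: _dt.date
    nautical_dawn: float | None
    sunrise: float | None
    sunset: float | None
    nautical_dusk: float | None
    noon: float
    prev_midnight: float
    next_midnight: float
    no_night: bool
    polar_day: bool
    polar_night: bool

    def as_timestamps(self) -> dict:
        def c(t):
            return None if t is None else pd.Timestamp(t, unit="s", tz="UTC")

        return {
            "nautical_dawn": c(self.nautical_dawn),
            "sunrise": c(self.sunrise),
            "sunset": c(self.sunset),
            "nautical_dusk": c(self.nautical_dusk),
        }


def solar_events(
    site: SiteConfig,
    anchor_date: _dt.date,
    twilight_threshold_deg: float = -12.0,
) -> SolarEvents:
    """Solve sunrise/sunset and nautical dawn/dusk for one local solar day.

    Morning events are searched between the previous solar midnight and solar
    noon of ``anchor_date``; evening events between noon and the next solar
    midnight.  Crossing instants are accurate to well under a second relative
    to the package ephemeris.
    """
    f = _elev_fn(site)
    t_utc_noon = (
        pd.Timestamp(anchor_date, tz="UTC").timestamp() + 43200.0 - site.longitude / 15.0 * 3600.0
    )
    grid = np.arange(t_utc_noon - 86400.0, t_utc_noon + 86400.0 + 60.0, 60.0)
    el = solar_elevation(site.latitude, site.longitude, grid)

    centre = (grid >= t_utc_noon - 43200.0) & (grid <= t_utc_noon + 43200.0)
    noon = _refine_extremum(site, float(grid[centre][np.argmax(el[centre])]), +1.0)
    before = grid <= noon
    after = grid >= noon
    prev_mid = _refine_extremum(site, float(grid[before][np.argmin(el[before])]), -1.0)
    after_grid = grid[after & (grid <= noon + 86400.0)]
    after_el = el[after & (grid <= noon + 86400.0)]
    next_mid = _refine_extremum(site, float(after_grid[np.argmin(after_el)]), -1.0)

    def morning(th):
        ups, _ = _grid_crossings(site, prev_mid, noon, th)
        return ups[-1] if ups else None

    def evening(th):
        _, downs = _grid_crossings(site, noon, next_mid, th)
        return downs[0] if downs else None

    sunrise = morning(0.0)
    sunset = evening(0.0)
    ndawn = morning(twilight_threshold_deg)
    ndusk = evening(twilight_threshold_deg)

    el_noon = f(noon)
    el_next_mid = f(next_mid)
    polar_day = sunrise is None and sunset is None and el_noon > 0.0
    polar_night = el_noon <= 0.0
    no_night = sunset is not None and el_next_mid > twilight_threshold_deg

    return SolarEvents(
        site_id=site.site_id,
        anchor_date=anchor_date,
        nautical_dawn=ndawn,
        sunrise=sunrise,
        sunset=sunset,
        nautical_dusk=ndusk,
        noon=noon,
        prev_midnight=prev_mid,
        next_midnight=next_mid,
        no_night=no_night,
        polar_day=polar_day,
        polar_night=polar_night,
    )


def crossing_times(
    site: SiteConfig, anchor_date: _dt.date, threshold_deg: float
) -> tuple[pd.Timestamp | None, pd.Timestamp | None]:
    """Morning up-crossing and evening down-crossing of a solar elevation
    threshold for one local solar day; ``None`` when absent.
    """
    if not -18.0 <= threshold_deg <= 10.0:
        # outside the range where "morning/evening crossing" is well defined
        ev = solar_events(site, anchor_date, twilight_threshold_deg=-12.0)
        up = down = None
        if threshold_deg < -18.0 or threshold_deg > 10.0:
            ups, _ = _grid_crossings(site, ev.prev_midnight, ev.noon, threshold_deg)
            _, downs = _grid_crossings(site, ev.noon, ev.next_midnight, threshold_deg)
            up = ups[-1] if ups else None
            down = downs[0] if downs else None
        c = lambda t: None if t is None else pd.Timestamp(t, unit="s", tz="UTC")
        return c(up), c(down)
    ev = solar_events(site, anchor_date, twilight_threshold_deg=threshold_deg)
    c = lambda t: None if t is None else pd.Timestamp(t, unit="s", tz="UTC")
    return c(ev.nautical_dawn), c(ev.nautical_dusk)


# ---------------------------------------------------------------------------
# diel-phase partition


@dataclass(frozen=True)
class DielPhaseInterval:
    """One labelled half-open interval [start, end) of a diel day."""

    site_id: str
    anchor_date: _dt.date
    phase: str
    start: float  # epoch seconds, UTC
    end: float

    @property
    def duration_s(self) -> float:
        return self.end - self.start

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start, unit="s", tz="UTC")

    @property
    def end_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.end, unit="s", tz="UTC")


def _diel_boundary(
    site: SiteConfig, date: _dt.date, threshold: float, _cache: dict | None = None
) -> float:
    """Start instant of the diel day anchored on ``date``.

    Nautical dawn when it exists; the sunset-to-sunrise twilight midpoint when
    the sun stays above the twilight threshold all night; solar midnight
    before noon for polar day/night.
    """
    ev = _cached_events(site, date, threshold, _cache)
    if ev.nautical_dawn is not None:
        return ev.nautical_dawn
    if ev.sunrise is not None:
        prev = _cached_events(site, date - _dt.timedelta(days=1), threshold, _cache)
        if prev.sunset is not None:
            return 0.5 * (prev.sunset + ev.sunrise)
    return ev.prev_midnight


def _cached_events(site, date, threshold, cache):
    if cache is None:
        return solar_events(site, date, threshold)
    key = (site.site_id, date, threshold)
    if key not in cache:
        cache[key] = solar_events(site, date, threshold)
    return cache[key]


def diel_phases(
    site: SiteConfig,
    anchor_date: _dt.date,
    config: RunConfig | None = None,
    _cache: dict | None = None,
) -> list[DielPhaseInterval]:
    """Partition one diel day into its phase intervals.

    The intervals are half-open, disjoint, ordered, and their union is
    exactly the diel day [B(d), B(d+1)) where B is the diel-day boundary
    (durations telescope exactly).  When no nautical night exists, three
    intervals are returned and the twilight span is split at its clock
    midpoint; under polar day a single 'day' interval is returned.
    """
    threshold = config.twilight_threshold_deg if config is not None else -12.0
    ev = _cached_events(site, anchor_date, threshold, _cache)
    b0 = _diel_boundary(site, anchor_date, threshold, _cache)
    b1 = _diel_boundary(site, anchor_date + _dt.timedelta(days=1), threshold, _cache)

    def iv(phase, start, end):
        return DielPhaseInterval(site.site_id, anchor_date, phase, start, end)

    out: list[DielPhaseInterval] = []
    if ev.sunrise is not None and ev.sunset is not None:
        if b0 < ev.sunrise:
            out.append(iv("crepuscular_morning", b0, ev.sunrise))
        out.append(iv("day", ev.sunrise, ev.sunset))
        if ev.nautical_dusk is not None and ev.nautical_dusk < b1:
            out.append(iv("crepuscular_evening", ev.sunset, ev.nautical_dusk))
            out.append(iv("night", ev.nautical_dusk, b1))
        else:
            # no nautical night: evening twilight runs to the midpoint b1
            out.append(iv("crepuscular_evening", ev.sunset, b1))
    elif ev.polar_day:
        out.append(iv("day", b0, b1))
    elif ev.nautical_dawn is not None or ev.nautical_dusk is not None:
        # polar night with twilight: sun crosses the twilight threshold but
        # never the horizon; rising side is morning, setting side evening
        start = b0
        if ev.noon > start:
            out.append(iv("crepuscular_morning", start, ev.noon))
            start = ev.noon
        if ev.nautical_dusk is not None and ev.nautical_dusk < b1:
            out.append(iv("crepuscular_evening", start, ev.nautical_dusk))
            out.append(iv("night", ev.nautical_dusk, b1))
        else:
            out.append(iv("crepuscular_evening", start, b1))
    else:
        out.append(iv("night", b0, b1))
    return out


def diel_phase_table(
    site: SiteConfig,
    start_date: _dt.date,
    end_date: _dt.date,
    config: RunConfig | None = None,
) -> list[DielPhaseInterval]:
    """Phase intervals for every anchor date in [start_date, end_date]."""
    cache: dict = {}
    out: list[DielPhaseInterval] = []
    d = start_date
    while d <= end_date:
        out.extend(diel_phases(site, d, config, _cache=cache))
        d += _dt.timedelta(days=1)
    return out


def assign_phase(timestamp, phase_intervals: Sequence[DielPhaseInterval]) -> tuple[str, _dt.date]:
    """Phase label and anchor date of the interval containing ``timestamp``.

    Intervals are half-open [start, end): a boundary instant belongs to the
    later interval.  Raises ``ValueError`` when the timestamp is not covered.
    """
    t = float(_to_epoch(timestamp))
    starts = np.array([p.start for p in phase_intervals])
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    i = int(np.searchsorted(starts, t, side="right")) - 1
    if i >= 0:
        p = phase_intervals[order[i]]
        if p.start <= t < p.end:
            return p.phase, p.anchor_date
    raise ValueError(f"timestamp {timestamp} not covered by any diel-phase interval")


def assign_phase_bulk(
    epochs: np.ndarray, phase_intervals: Sequence[DielPhaseInterval]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised phase assignment; returns (phase labels, interval indices).

    Timestamps outside all intervals get label '' and index -1.
    """
    ivs = sorted(phase_intervals, key=lambda p: p.start)
    starts = np.array([p.start for p in ivs])
    ends = np.array([p.end for p in ivs])
    labels = np.array([p.phase for p in ivs])
    idx = np.searchsorted(starts, epochs, side="right") - 1
    ok = (idx >= 0) & (epochs < ends[np.clip(idx, 0, None)])
    out = np.where(ok, labels[np.clip(idx, 0, None)], "")
    src = np.where(ok, idx, -1)
    return out, src


def phases_to_frame(intervals: Iterable[DielPhaseInterval]) -> pd.DataFrame:
    """Phase intervals as a frame with the phases.csv schema."""
    rows = [
        {
            "site_id": p.site_id,
            "anchor_date": p.anchor_date.isoformat(),
            "phase": p.phase,
            "start_utc": p.start_ts,
            "end_utc": p.end_ts,
            "duration_s": p.duration_s,
        }
        for p in intervals
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "anchor_date", "phase", "start_utc", "end_utc", "duration_s"]
    )
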