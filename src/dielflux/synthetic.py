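"""Synthetic radar-echo generator with exported ground truth.

The generator emulates the statistical structure the analysis assumes: a
diel activity profile tied to solar elevation (low after sunrise, a broad
midday peak, a pronounced dusk peak at about -6 deg on the setting side, a
smaller dawn peak on the rising side, and a low nocturnal floor), modulated
by a Gaussian seasonal envelope; lognormal radar cross sections with a
heavier night component; gamma-distributed flight altitudes shifted upward
at night; classifier probability noise; bird/non-biological contaminants;
and rain and monitoring-outage intervals.

Echo times are drawn from an inhomogeneous Poisson process by thinning
against a gridded envelope of the intensity. Detection is thinned by the
same geometric transect width w(h) that the traffic module uses as weight,
so the migration-traffic estimator is exact in expectation. Insects do not
fly during simulated rain (the intensity is zero there), matching the
pipeline's rain-as-zero-traffic rule. Ground truth per site, diel day and
phase is obtained by Riemann integration of the intensity and stored with
the dataset.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from dielflux.io_core import (
    RunConfig,
    SiteConfig,
    merge_spans,
    write_echo_frame,
    write_intervals,
    write_sites,
)
from dielflux.solar import diel_phase_table, solar_elevation
from dielflux.solar import _to_epoch as _solar_to_epoch
from dielflux.traffic import transect_width

__all__ = ["SimParams", "diel_intensity", "simulate_site", "simulate_network"]


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults are the emulated study conditions.

    Fluxes are in insects km^-1 h^-1 (the scale the traffic estimator
    recovers).  The seasonal envelope is a Gaussian in day-of-year peaking in
    mid-July.  Diel weights multiply the envelope: ``a_day`` scales a
    sin(elevation)^k daytime term, ``a_dusk``/``a_dawn`` scale Gaussian
    twilight peaks centred at ``twilight_peak_elev_deg`` on the setting and
    rising side respectively, and ``a_night`` is the nocturnal floor below
    -12 deg.  RCS is lognormal with a night median multiplier > 1; altitudes
    are gamma with an additive night shift, truncated to the analysis band.
    """

    seed: int
    start_date: _dt.date = _dt.date(2021, 3, 1)
    end_date: _dt.date = _dt.date(2021, 10, 31)

    peak_flux: float = 400.0
    season_center_doy: float = 195.0
    season_width_days: float = 60.0
    constant_flux: float | None = None  # overrides the diel/seasonal profile

    a_day: float = 1.0
    a_dusk: float = 2.5
    a_dawn: float = 0.5
    a_night: float = 0.15
    day_exponent: float = 2.0
    twilight_peak_elev_deg: float = -6.0
    twilight_peak_width_deg: float = 3.0

    rcs_median_day_cm2: float = 0.05
    rcs_night_multiplier: float = 4.0
    rcs_sigma_log: float = 0.8

    alt_gamma_shape: float = 6.0
    alt_mean_day_m: float = 160.0
    night_alt_shift_m: float = 40.0
    alt_band: tuple[float, float] = (50.0, 500.0)

    rain_per_day: float = 0.3
    rain_mean_hours: float = 2.0
    outage_per_day: float = 0.05
    outage_mean_hours: float = 3.0

    contam_bird_frac: float = 0.05
    contam_nonbio_frac: float = 0.05
    insect_p_mean: float = 0.75
    insect_p_conc: float = 20.0

    def __post_init__(self) -> None:
        for name in ("a_day", "a_dusk", "a_dawn", "a_night"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.start_date > self.end_date:
            raise ValueError("start_date after end_date")


def _doy(epoch: np.ndarray) -> np.ndarray:
    days = np.floor(epoch / 86400.0).astype("int64")
    dates = days.astype("datetime64[D]")
    years = dates.astype("datetime64[Y]")
    return (dates - years).astype(float) + 1.0


def _season(doy: np.ndarray, params: SimParams) -> np.ndarray:
    return params.peak_flux * np.exp(
        -0.5 * ((doy - params.season_center_doy) / params.season_width_days) ** 2
    )


def diel_intensity(site: SiteConfig, timestamp, params: SimParams):
    """Instantaneous migration flux lambda(t) in insects km^-1 h^-1.

    lambda(t) = S(doy) [ a_day max(0, sin e)^k
                         + a_dusk g(e) 1_setting + a_dawn g(e) 1_rising
                         + a_night 1_{e < -12 deg} ]
    with g a Gaussian in elevation degrees.  ``constant_flux`` short-circuits
    the whole profile.  Rain zeroing is applied by the simulator, not here.
    """
    ep = _solar_to_epoch(timestamp)
    scalar = np.isscalar(ep)
    epoch = np.atleast_1d(np.asarray(ep, dtype=float))
    if params.constant_flux is not None:
        out = np.full(epoch.shape, float(params.constant_flux))
        return float(out[0]) if scalar else out
    e = solar_elevation(site.latitude, site.longitude, epoch)
    e_next = solar_elevation(site.latitude, site.longitude, epoch + 30.0)
    rising = e_next > e
    g = np.exp(
        -0.5 * ((e - params.twilight_peak_elev_deg) / params.twilight_peak_width_deg) ** 2
    )
    lam = (
        params.a_day * np.maximum(0.0, np.sin(np.deg2rad(e))) ** params.day_exponent
        + params.a_dusk * g * (~rising)
        + params.a_dawn * g * rising
        + params.a_night * (e < -12.0)
    )
    out = _season(_doy(epoch), params) * lam
    return float(out[0]) if scalar else out


def _intensity_epochs(site: SiteConfig, epochs: np.ndarray, params: SimParams) -> np.ndarray:
    if params.constant_flux is not None:
        return np.full(epochs.shape, float(params.constant_flux))
    return diel_intensity(site, epochs, params)


def _draw_intervals(
    rng: np.random.Generator, t0: float, t1: float, per_day: float, mean_hours: float
) -> np.ndarray:
    days = (t1 - t0) / 86400.0
    k = rng.poisson(per_day * days)
    if k == 0:
        return np.empty((0, 2))
    starts = rng.uniform(t0, t1, size=k)
    durs = rng.exponential(mean_hours * 3600.0, size=k)
    spans = np.column_stack([starts, np.minimum(starts + durs, t1)])
    return merge_spans(spans[spans[:, 1] > spans[:, 0]])


def _complement(spans: np.ndarray, t0: float, t1: float) -> np.ndarray:
    out = []
    cur = t0
    for s, e in spans:
        if s > cur:
            out.append([cur, min(s, t1)])
        cur = max(cur, e)
    if cur < t1:
        out.append([cur, t1])
    return np.array(out) if out else np.empty((0, 2))


def _in_spans(t: np.ndarray, spans: np.ndarray) -> np.ndarray:
    if len(spans) == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(spans[:, 0], t, side="right") - 1
    ok = idx >= 0
    out = np.zeros(t.shape, dtype=bool)
    out[ok] = t[ok] < spans[idx[ok], 1]
    return out


def _regime(site: SiteConfig, epochs: np.ndarray) -> np.ndarray:
    """0 = day (e > 0), 1 = crepuscular, 2 = night (e < -12)."""
    e = solar_elevation(site.latitude, site.longitude, epochs)
    return np.where(e > 0.0, 0, np.where(e < -12.0, 2, 1))


def _alt_shift(params: SimParams, regime: np.ndarray) -> np.ndarray:
    return params.night_alt_shift_m * np.array([0.0, 0.5, 1.0])[regime]


def _sample_altitudes(
    rng: np.random.Generator, params: SimParams, regime: np.ndarray
) -> np.ndarray:
    """Shifted-gamma altitudes rejection-truncated to the analysis band."""
    shape = params.alt_gamma_shape
    scale = (params.alt_mean_day_m - 0.0) / shape
    shift = _alt_shift(params, regime)
    lo, hi = params.alt_band
    h = shift + rng.gamma(shape, scale, size=regime.size)
    for _ in range(200):
        bad = (h < lo) | (h > hi)
        if not bad.any():
            break
        h[bad] = shift[bad] + rng.gamma(shape, scale, size=int(bad.sum()))
    return np.clip(h, lo, hi)


def _truncated_gamma_stats(params: SimParams, shift: float) -> tuple[float, float]:
    """(mean, median) of the shifted gamma truncated to the analysis band."""
    shape = params.alt_gamma_shape
    scale = params.alt_mean_day_m / shape
    lo, hi = params.alt_band
    dist = _gamma_dist(shape, loc=shift, scale=scale)
    c_lo, c_hi = dist.cdf(lo), dist.cdf(hi)
    x = np.linspace(lo, hi, 4001)
    pdf = dist.pdf(x) / (c_hi - c_lo)
    mean = float(np.trapezoid(pdf * x, x))
    median = float(dist.ppf(c_lo + 0.5 * (c_hi - c_lo)))
    return mean, median


def _quantize_probs(p_insect, p_bird, p_nonbio, decimals: int = 4):
    """Round class probabilities without letting the sum exceed 1."""
    p = np.round(p_insect, decimals)
    b = np.round(p_bird, decimals)
    nb = np.round(p_nonbio, decimals)
    excess = np.round(p + b + nb - 1.0, decimals)
    nb = np.clip(np.where(excess > 0, nb - excess, nb), 0.0, 1.0)
    return p, b, np.round(nb, decimals)


def _sample_insect_probs(rng: np.random.Generator, n: int, params: SimParams):
    """Insect class probabilities: noisy but always identifiable.

    p_insect is beta-distributed, confined above 0.5 so a true insect always
    passes the threshold-and-argmax filter (detection is thinned by w(h)
    only; classification never removes a truth insect).  The remainder is
    split randomly between the bird and non-biological classes.
    """
    a = params.insect_p_mean * params.insect_p_conc
    b = (1.0 - params.insect_p_mean) * params.insect_p_conc
    p = rng.beta(a, b, size=n)
    for _ in range(100):
        bad = p <= 0.501
        if not bad.any():
            break
        p[bad] = rng.beta(a, b, size=int(bad.sum()))
    p = np.clip(p, 0.502, 0.999)
    rest = 1.0 - p
    u = rng.uniform(0.0, 1.0, size=n)
    return p, rest * u, rest * (1.0 - u)


def simulate_site(
    site: SiteConfig, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one site; returns (echoes, intervals, truth) frames.

    Echo times come from thinning a homogeneous Poisson candidate stream
    against a 1-min-gridded envelope of lambda(t) (with a safety margin) and
    the transect-width detection probability w(h)/w_max.  Echoes are only
    emitted inside short-pulse protocol windows (the complement of simulated
    outages).  Truth totals per diel day and phase integrate
    lambda(t) 1_{no rain} on a 10 s grid.
    """
    rng = np.random.default_rng(params.seed)
    t0 = pd.Timestamp(params.start_date, tz="UTC").timestamp()
    t1 = pd.Timestamp(params.end_date, tz="UTC").timestamp() + 86400.0

    outages = _draw_intervals(rng, t0, t1, params.outage_per_day, params.outage_mean_hours)
    protocol = _complement(outages, t0, t1)
    rain = _draw_intervals(rng, t0, t1, params.rain_per_day, params.rain_mean_hours)

    # envelope of lambda on a 1-min grid, with margin for between-grid maxima
    grid = np.arange(t0, t1, 60.0)
    lam_grid = _intensity_epochs(site, grid, params)
    lam_bound = float(lam_grid.max()) * 1.05 + 1e-12

    lo, hi = params.alt_band
    w_max = transect_width(hi)
    duration_h = (t1 - t0) / 3600.0
    n_cand = rng.poisson(lam_bound * w_max * duration_h)

    t_cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    u_time = rng.uniform(0.0, 1.0, size=n_cand)
    lam_cand = _intensity_epochs(site, t_cand, params)
    lam_cand[_in_spans(t_cand, rain)] = 0.0
    keep = (u_time * lam_bound < lam_cand) & _in_spans(t_cand, protocol)
    t_ins = t_cand[keep]

    regime = _regime(site, t_ins)
    h_ins = _sample_altitudes(rng, params, regime)
    u_alt = rng.uniform(0.0, 1.0, size=t_ins.size)
    det = u_alt * w_max < transect_width(np.maximum(h_ins, 1e-9))
    t_ins, regime, h_ins = t_ins[det], regime[det], h_ins[det]

    log_med = np.log(params.rcs_median_day_cm2) + np.log(params.rcs_night_multiplier) * (
        0.5 * (regime == 1) + 1.0 * (regime == 2)
    )
    rcs_ins = np.exp(log_med + params.rcs_sigma_log * rng.standard_normal(t_ins.size))
    p_ins, p_bird_i, p_nonbio_i = _quantize_probs(
        *_sample_insect_probs(rng, t_ins.size, params)
    )

    frames = [
        pd.DataFrame(
            {
                "site_id": site.site_id,
                "timestamp_utc": pd.to_datetime(np.round(t_ins), unit="s", utc=True),
                "altitude_agl_m": np.round(h_ins, 1),
                "p_insect": p_ins,
                "p_bird": p_bird_i,
                "p_nonbio": p_nonbio_i,
                "rcs_max_cm2": np.round(rcs_ins, 6),
                "truth_label": "insect",
            }
        )
    ]

    # contaminants: birds (half of them insect-ambiguous, exercising the
    # argmax rule) and non-biological clutter; never pass the insect filter
    n_exp = max(float(t_ins.size), 1.0)
    for label, frac in (("bird", params.contam_bird_frac), ("nonbio", params.contam_nonbio_frac)):
        k = rng.poisson(frac * n_exp)
        if k == 0:
            continue
        t_c = rng.uniform(t0, t1, size=k)
        ok = _in_spans(t_c, protocol)
        t_c = t_c[ok]
        k = t_c.size
        if k == 0:
            continue
        h_c = rng.uniform(20.0, 900.0, size=k)
        rcs_c = np.exp(np.log(0.5) + 1.0 * rng.standard_normal(k))
        ambiguous = (label == "bird") & (rng.uniform(size=k) < 0.5)
        p_i = np.where(ambiguous, rng.uniform(0.41, 0.49, size=k), rng.uniform(0.0, 0.35, size=k))
        p_main = rng.uniform(0.51, 0.95, size=k)
        p_main = np.minimum(p_main, 1.0 - p_i - 1e-4)
        p_main = np.maximum(p_main, p_i + 1e-4)  # contaminant class wins argmax
        p_rest = np.maximum(1.0 - p_i - p_main, 0.0)
        p_i, p_b, p_nb = _quantize_probs(
            p_i,
            p_main if label == "bird" else p_rest,
            p_main if label == "nonbio" else p_rest,
        )
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site.site_id,
                    "timestamp_utc": pd.to_datetime(np.round(t_c), unit="s", utc=True),
                    "altitude_agl_m": np.round(h_c, 1),
                    "p_insect": p_i,
                    "p_bird": p_b,
                    "p_nonbio": p_nb,
                    "rcs_max_cm2": np.round(rcs_c, 6),
                    "truth_label": label,
                }
            )
        )

    echoes = pd.concat(frames, ignore_index=True)
    echoes = echoes.sort_values("timestamp_utc", kind="stable").reset_index(drop=True)

    interval_rows = []
    for kind, spans in (("protocol_shortpulse", protocol), ("rain", rain)):
        for s, e in spans:
            interval_rows.append(
                {
                    "site_id": site.site_id,
                    "kind": kind,
                    "start_utc": pd.Timestamp(round(s), unit="s", tz="UTC"),
                    "end_utc": pd.Timestamp(round(e), unit="s", tz="UTC"),
                }
            )
    intervals = pd.DataFrame(
        interval_rows, columns=["site_id", "kind", "start_utc", "end_utc"]
    )

    truth = _integrate_truth(site, params, rain)
    return echoes, intervals, truth


def _integrate_truth(
    site: SiteConfig, params: SimParams, rain: np.ndarray, step: float = 10.0
) -> pd.DataFrame:
    """Expected totals, rates, RCS medians and altitude means per diel phase."""
    phases = diel_phase_table(site, params.start_date, params.end_date)
    t0 = pd.Timestamp(params.start_date, tz="UTC").timestamp()
    t1 = pd.Timestamp(params.end_date, tz="UTC").timestamp() + 86400.0

    regime_of_phase = {"day": 0, "crepuscular_morning": 1, "crepuscular_evening": 1, "night": 2}
    alt_stats = {
        r: _truncated_gamma_stats(params, params.night_alt_shift_m * s)
        for r, s in ((0, 0.0), (1, 0.5), (2, 1.0))
    }
    rcs_med = {
        r: params.rcs_median_day_cm2 * params.rcs_night_multiplier**s
        for r, s in ((0, 0.0), (1, 0.5), (2, 1.0))
    }

    rows = []
    for p in phases:
        a, b = max(p.start, t0), min(p.end, t1)
        if b <= a:
            total = np.nan
        else:
            grid = np.arange(a, b, step)
            lam = _intensity_epochs(site, grid + 0.5 * step, params)
            lam[_in_spans(grid + 0.5 * step, rain)] = 0.0
            total = float(lam.sum() * step / 3600.0)
        duration_h = (p.end - p.start) / 3600.0
        reg = regime_of_phase[p.phase]
        rows.append(
            {
                "site_id": p.site_id,
                "anchor_date": p.anchor_date.isoformat(),
                "phase": p.phase,
                "true_total_traffic": total,
                "true_mean_rate": total / duration_h if np.isfinite(total) else np.nan,
                "duration_h": duration_h,
                "true_rcs_median_cm2": rcs_med[reg],
                "true_alt_mean_m": alt_stats[reg][0],
                "true_alt_median_m": alt_stats[reg][1],
            }
        )
    return pd.DataFrame(rows)


def simulate_network(
    sites: Sequence[SiteConfig],
    params: SimParams | Mapping[str, SimParams],
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate several sites with independent, stably sub-seeded streams.

    Each site's stream is derived from the master seed and a CRC of its
    site_id, so adding or reordering sites never perturbs the others.  When
    ``out_dir`` is given, writes echoes.csv, intervals.csv, truth.csv and
    sites.csv there.
    """
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate site_id in network")
    echo_frames, interval_frames, truth_frames = [], [], []
    for site in sites:
        p = params[site.site_id] if isinstance(params, Mapping) else params
        child = np.random.SeedSequence(
            entropy=p.seed, spawn_key=(zlib.crc32(site.site_id.encode()),)
        )
        site_seed = int(child.generate_state(1)[0] % (2**31))
        e, iv, tr = simulate_site(site, dataclasses.replace(p, seed=site_seed))
        echo_frames.append(e)
        interval_frames.append(iv)
        truth_frames.append(tr)
    echoes = pd.concat(echo_frames, ignore_index=True)
    intervals = pd.concat(interval_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_echo_frame(echoes, out / "echoes.csv")
        write_intervals(intervals, out / "intervals.csv")
        truth.to_csv(out / "truth.csv", index=False)
        write_sites(list(sites), out / "sites.csv")
    return echoes, intervals, truth
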