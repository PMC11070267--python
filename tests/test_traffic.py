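import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dielflux.io_core import RunConfig, SiteConfig
from dielflux.solar import DielPhaseInterval
from dielflux.traffic import (
    effective_minutes,
    filter_insects,
    hourly_mtr,
    phase_aggregates,
    transect_width,
)

UNIT_W = lambda h: np.ones_like(np.asarray(h, dtype=float))  # constant 1 km hook


def _ts(s):
    return pd.Timestamp(s, tz="UTC")


_ECHO_COLS = [
    "site_id",
    "timestamp_utc",
    "altitude_agl_m",
    "p_insect",
    "p_bird",
    "p_nonbio",
    "rcs_max_cm2",
]


def _echoes(rows):
    if not rows:
        df = pd.DataFrame(columns=_ECHO_COLS)
        df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], utc=True)
        return df
    return pd.DataFrame(
        [
            {
                "site_id": "a",
                "timestamp_utc": _ts(t),
                "altitude_agl_m": h,
                "p_insect": pi,
                "p_bird": pb,
                "p_nonbio": pn,
                "rcs_max_cm2": 0.05,
            }
            for t, h, pi, pb, pn in rows
        ]
    )


def _proto(start, end, site="a", kind="protocol_shortpulse"):
    return pd.DataFrame(
        {"site_id": [site], "kind": [kind], "start_utc": [_ts(start)], "end_utc": [_ts(end)]}
    )


class TestFilter:
    @pytest.mark.parametrize(
        "p_insect,p_bird,p_nonbio,alt,kept",
        [
            (0.5, 0.3, 0.2, 200.0, True),  # clears threshold and argmax
            (0.45, 0.5, 0.05, 200.0, False),  # >0.4 but bird wins argmax
            (0.9, 0.05, 0.05, 30.0, False),  # below the 50 m band floor
            (0.9, 0.05, 0.05, 600.0, False),  # above the 500 m ceiling
            (0.4, 0.3, 0.3, 200.0, False),  # threshold is strict
            (0.41, 0.41, 0.18, 200.0, False),  # tie with bird is not "higher"
        ],
    )
    def test_threshold_argmax_and_band(self, p_insect, p_bird, p_nonbio, alt, kept):
        df = _echoes([("2021-06-01T12:00:00", alt, p_insect, p_bird, p_nonbio)])
        out = filter_insects(df, RunConfig())
        assert (len(out) == 1) == kept


class TestTransectWidth:
    def test_direct_evaluation_200m(self):
        assert transect_width(200.0) == pytest.approx(0.06157, abs=5e-5)

    def test_linearity(self):
        assert transect_width(400.0) == pytest.approx(2 * transect_width(200.0))
        assert transect_width(500.0) / transect_width(50.0) == pytest.approx(10.0)

    def test_nonpositive_altitude_rejected(self):
        with pytest.raises(ValueError):
            transect_width(0.0)


class TestEffectiveMinutes:
    def test_full_hour(self):
        iv = _proto("2021-06-01T08:00:00", "2021-06-01T09:00:00")
        assert effective_minutes(iv, "a", _ts("2021-06-01T08:00:00")) == 60.0

    def test_partial_window(self):
        iv = _proto("2021-06-01T08:00:00", "2021-06-01T08:10:00")
        assert effective_minutes(iv, "a", _ts("2021-06-01T08:00:00")) == 10.0

    def test_random_windows_match_minute_oracle(self):
        rng = np.random.default_rng(9)
        base = _ts("2021-06-01T08:00:00").timestamp()
        rows = []
        covered = np.zeros(60, dtype=bool)
        for _ in range(10):
            a = int(rng.integers(-30, 80))
            d = int(rng.integers(1, 40))
            rows.append(
                {
                    "site_id": "a",
                    "kind": "protocol_shortpulse",
                    "start_utc": pd.Timestamp(base + a * 60, unit="s", tz="UTC"),
                    "end_utc": pd.Timestamp(base + (a + d) * 60, unit="s", tz="UTC"),
                }
            )
            covered[np.clip(a, 0, 60) : np.clip(a + d, 0, 60)] = True
        got = effective_minutes(pd.DataFrame(rows), "a", _ts("2021-06-01T08:00:00"))
        assert got == pytest.approx(covered.sum())


class TestHourlyMTR:
    CFG = RunConfig(period=(dt.date(2021, 6, 1), dt.date(2021, 6, 1)))

    def test_three_echoes_unit_width_full_hour(self):
        ech = _echoes(
            [("2021-06-01T08:%02d:00" % m, 200.0, 0.9, 0.05, 0.05) for m in (5, 20, 40)]
        )
        iv = _proto("2021-06-01T00:00:00", "2021-06-02T00:00:00")
        out = hourly_mtr(ech, iv, SiteConfig("a", "A", 47.0, 8.0), self.CFG, width_km=UNIT_W)
        row = out[out["hour_start_utc"] == _ts("2021-06-01T08:00:00")].iloc[0]
        assert row["mtr"] == pytest.approx(3.0)
        assert row["n_echoes"] == 3

    def test_single_echo_geometric_width(self):
        ech = _echoes([("2021-06-01T08:30:00", 200.0, 0.9, 0.05, 0.05)])
        iv = _proto("2021-06-01T00:00:00", "2021-06-02T00:00:00")
        out = hourly_mtr(ech, iv, SiteConfig("a", "A", 47.0, 8.0), self.CFG)
        row = out[out["hour_start_utc"] == _ts("2021-06-01T08:00:00")].iloc[0]
        assert row["mtr"] == pytest.approx(16.24, abs=0.02)

    def test_under_12_minutes_is_missing(self):
        ech = _echoes([("2021-06-01T08:05:00", 200.0, 0.9, 0.05, 0.05)])
        iv = _proto("2021-06-01T08:00:00", "2021-06-01T08:10:00")
        out = hourly_mtr(ech, iv, SiteConfig("a", "A", 47.0, 8.0), self.CFG)
        row = out[out["hour_start_utc"] == _ts("2021-06-01T08:00:00")].iloc[0]
        assert np.isnan(row["mtr"])
        assert row["effective_min"] == pytest.approx(10.0)

    def test_rain_echoes_excluded_but_time_kept(self):
        ech = _echoes(
            [("2021-06-01T08:%02d:00" % m, 200.0, 0.9, 0.05, 0.05) for m in (5, 20, 40)]
        )
        iv = pd.concat(
            [
                _proto("2021-06-01T00:00:00", "2021-06-02T00:00:00"),
                _proto("2021-06-01T08:15:00", "2021-06-01T08:30:00", kind="rain"),
            ],
            ignore_index=True,
        )
        out = hourly_mtr(ech, iv, SiteConfig("a", "A", 47.0, 8.0), self.CFG, width_km=UNIT_W)
        row = out[out["hour_start_utc"] == _ts("2021-06-01T08:00:00")].iloc[0]
        assert row["mtr"] == pytest.approx(2.0)  # the 08:20 echo fell in rain
        assert row["effective_min"] == 60.0


class TestPhaseAggregates:
    CFG = RunConfig(period=(dt.date(2021, 6, 1), dt.date(2021, 6, 1)))

    def _phase(self, start, end, phase="day"):
        return DielPhaseInterval(
            "a", dt.date(2021, 6, 1), phase, _ts(start).timestamp(), _ts(end).timestamp()
        )

    def test_monitored_empty_phase_is_zero(self):
        iv = _proto("2021-06-01T00:00:00", "2021-06-02T00:00:00")
        ph = [self._phase("2021-06-01T20:00:00", "2021-06-02T04:00:00", "night")]
        out = phase_aggregates(_echoes([]), ph, iv, self.CFG, width_km=UNIT_W)
        assert out.loc[0, "mean_rate"] == 0.0
        assert out.loc[0, "total_traffic"] == 0.0

    def test_unit_width_arithmetic(self):
        rows = [
            ("2021-06-01T%02d:10:00" % h, 200.0, 0.9, 0.05, 0.05) for h in range(6, 18)
        ] * 2
        iv = _proto("2021-06-01T00:00:00", "2021-06-02T00:00:00")
        ph = [self._phase("2021-06-01T06:00:00", "2021-06-01T18:00:00", "day")]
        out = phase_aggregates(_echoes(rows), ph, iv, self.CFG, width_km=UNIT_W)
        assert out.loc[0, "mean_rate"] == pytest.approx(2.0)  # 24 echoes / 12 h
        assert out.loc[0, "total_traffic"] == pytest.approx(24.0)

    def test_low_monitoring_missing(self):
        iv = _proto("2021-06-01T06:00:00", "2021-06-01T08:00:00")  # 2 of 12 h < 20%
        ph = [self._phase("2021-06-01T06:00:00", "2021-06-01T18:00:00", "day")]
        out = phase_aggregates(_echoes([]), ph, iv, self.CFG, width_km=UNIT_W)
        assert np.isnan(out.loc[0, "mean_rate"])

    def test_total_equals_rate_times_duration(self):
        rng = np.random.default_rng(2)
        rows = [
            (
                pd.Timestamp(
                    _ts("2021-06-01T06:00:00").timestamp() + float(rng.uniform(0, 12 * 3600)),
                    unit="s",
                    tz="UTC",
                ).isoformat(),
                float(rng.uniform(60, 450)),
                0.9,
                0.05,
                0.05,
            )
            for _ in range(50)
        ]
        iv = _proto("2021-06-01T05:00:00", "2021-06-01T18:00:00")
        ph = [self._phase("2021-06-01T06:00:00", "2021-06-01T18:00:00", "day")]
        out = phase_aggregates(_echoes(rows), ph, iv, self.CFG)
        assert out.loc[0, "total_traffic"] == pytest.approx(
            out.loc[0, "mean_rate"] * out.loc[0, "duration_h"], rel=1e-9
        )

    def test_rain_removes_exactly_covered_echoes(self):
        rows = [("2021-06-01T%02d:30:00" % h, 200.0, 0.9, 0.05, 0.05) for h in range(6, 18)]
        ph = [self._phase("2021-06-01T06:00:00", "2021-06-01T18:00:00", "day")]
        iv_dry = _proto("2021-06-01T00:00:00", "2021-06-02T00:00:00")
        iv_rain = pd.concat(
            [iv_dry, _proto("2021-06-01T10:00:00", "2021-06-01T12:00:00", kind="rain")],
            ignore_index=True,
        )
        dry = phase_aggregates(_echoes(rows), ph, iv_dry, self.CFG, width_km=UNIT_W)
        wet = phase_aggregates(_echoes(rows), ph, iv_rain, self.CFG, width_km=UNIT_W)
        # 2 echoes (10:30, 11:30) removed; effective time unchanged
        assert dry.loc[0, "mean_rate"] * 12 - wet.loc[0, "mean_rate"] * 12 == pytest.approx(2.0)
        assert wet.loc[0, "effective_h"] == dry.loc[0, "effective_h"]


class TestEstimatorRecovery:
    def test_constant_flux_mtr_unbiased(self):
        """Poisson echoes thinned by w(h) recover F insects/km/h via 1/w weights."""
        import datetime as dtm

        from dielflux.synthetic import SimParams, simulate_site

        site = SiteConfig("a", "A", 47.0, 8.0)
        params = SimParams(
            seed=123,
            start_date=dtm.date(2021, 6, 1),
            end_date=dtm.date(2021, 6, 21),
            constant_flux=50.0,
            rain_per_day=0.0,
            outage_per_day=0.0,
        )
        echoes, intervals, _ = simulate_site(site, params)
        cfg = RunConfig(period=(dtm.date(2021, 6, 1), dtm.date(2021, 6, 21)))
        insects = echoes[echoes["truth_label"] == "insect"]
        out = hourly_mtr(insects, intervals, site, cfg)
        mtr = out["mtr"].dropna()
        assert len(mtr) >= 500
        # SE of the mean of the hourly estimates
        se = mtr.std(ddof=1) / np.sqrt(len(mtr))
        assert abs(mtr.mean() - 50.0) < 3 * se
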