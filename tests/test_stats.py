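import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from dielflux.stats import (
    compress_proportion,
    daily_proportions,
    fit_beta_groups,
    holm_adjust,
    omnibus_test,
    pairwise_posthoc,
)


class TestDailyProportions:
    def _agg(self, rates, totals=None, durations=None):
        phases = ["crepuscular_morning", "day", "crepuscular_evening", "night"]
        durations = durations or [1.0, 14.0, 1.0, 8.0]
        totals = totals or [r * d for r, d in zip(rates, durations)]
        return pd.DataFrame(
            {
                "site_id": "a",
                "anchor_date": "2021-06-01",
                "phase": phases,
                "mean_rate": rates,
                "total_traffic": totals,
                "duration_h": durations,
                "effective_h": durations,
            }
        )

    def test_intensity_shares(self):
        out = daily_proportions(self._agg([10.0, 60.0, 20.0, 10.0]))
        got = dict(zip(out["phase"], out["prop_intensity"]))
        assert got == pytest.approx(
            {"crepuscular_morning": 0.1, "day": 0.6, "crepuscular_evening": 0.2, "night": 0.1}
        )
        assert out["prop_intensity"].sum() == pytest.approx(1.0)
        assert out["prop_traffic"].sum() == pytest.approx(1.0)

    def test_all_zero_day_is_missing(self):
        out = daily_proportions(self._agg([0.0, 0.0, 0.0, 0.0]))
        assert out["prop_intensity"].isna().all()
        assert not out["complete"].any()

    def test_symmetric_totals(self):
        out = daily_proportions(self._agg([1.0, 1.0, 1.0, 1.0], totals=[1.0] * 4))
        assert np.allclose(out["prop_traffic"], 0.25)

    def test_missing_phase_aggregate_makes_day_missing(self):
        agg = self._agg([10.0, 60.0, 20.0, 10.0])
        agg.loc[3, "mean_rate"] = np.nan
        out = daily_proportions(agg)
        assert not out["complete"].any()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            daily_proportions(self._agg([-1.0, 1.0, 1.0, 1.0]))


class TestCompression:
    def test_fixed_point_and_direct_values(self):
        assert compress_proportion(0.5, 7) == pytest.approx(0.5)
        assert compress_proportion(0.5, 1000) == pytest.approx(0.5)
        assert compress_proportion(0.0, 100) == pytest.approx(0.005)
        assert compress_proportion(1.0, 10) == pytest.approx(0.95)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            compress_proportion(0.5, 0)

    @given(st.floats(0.0, 1.0), st.integers(1, 10000))
    @settings(max_examples=200, deadline=None)
    def test_maps_into_open_interval_and_monotone(self, y, n):
        yc = compress_proportion(y, n)
        assert 0.0 < yc < 1.0
        # strictly increasing for n >= 2 (n = 1 collapses to the 0.5 fixed point)
        if n >= 2 and y + 1e-3 <= 1.0:
            assert compress_proportion(y + 1e-3, n) > yc

    def test_converges_to_identity(self):
        y = np.array([0.1, 0.37, 0.8])
        assert np.abs(compress_proportion(y, 10**7) - y).max() < 1e-6


class TestBetaFit:
    def test_single_group_symmetric_values(self):
        fit = fit_beta_groups([0.3, 0.7], ["a", "a"])
        assert fit.mu[0] == pytest.approx(0.5, abs=1e-6)

    def test_identical_groups_identical_means(self):
        vals = [0.2, 0.4, 0.6, 0.8] * 2
        labels = ["a"] * 4 + ["b"] * 4
        fit = fit_beta_groups(vals, labels)
        assert fit.mu[0] == pytest.approx(fit.mu[1], abs=1e-6)

    def test_parameter_recovery_seeded(self):
        rng = np.random.default_rng(100)
        y = rng.beta(0.6 * 20, 0.4 * 20, size=500)
        fit = fit_beta_groups(y, np.repeat("g", 500))
        assert fit.mu[0] == pytest.approx(0.6, abs=0.05)
        assert fit.phi == pytest.approx(20.0, rel=0.30)
        assert fit.converged

    def test_recovery_across_mean_grid(self):
        rng = np.random.default_rng(200)
        for mu in np.arange(0.1, 0.95, 0.1):
            y = rng.beta(mu * 15, (1 - mu) * 15, size=500)
            fit = fit_beta_groups(y, np.repeat("g", 500))
            assert fit.mu[0] == pytest.approx(mu, abs=0.05)

    def test_boundary_values_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="compress_proportion"):
            fit_beta_groups([0.0, 0.5, 0.5], ["a"] * 3)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_groups([0.5], ["a"])


class TestOmnibus:
    def test_identical_groups_null(self):
        vals = np.tile([0.3, 0.4, 0.6, 0.7], 3)
        labels = np.repeat(["a", "b", "c"], 4)
        out = omnibus_test(vals, labels)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-6)
        assert out["p"] == pytest.approx(1.0, abs=1e-6)
        assert out["df"] == 2

    def test_large_separation_tiny_p(self):
        rng = np.random.default_rng(8)
        y1 = rng.beta(0.2 * 50, 0.8 * 50, 100)
        y2 = rng.beta(0.8 * 50, 0.2 * 50, 100)
        out = omnibus_test(np.r_[y1, y2], np.repeat(["a", "b"], 100))
        assert out["p"] < 1e-6

    def test_full_likelihood_at_least_null(self):
        rng = np.random.default_rng(55)
        vals = rng.beta(3, 3, 60)
        labels = np.repeat(["a", "b", "c"], 20)
        assert omnibus_test(vals, labels)["statistic"] >= 0.0


class TestPairwise:
    def test_14_groups_yield_91_results(self):
        rng = np.random.default_rng(31)
        vals = rng.beta(5, 5, 14 * 10)
        labels = np.repeat([f"s{i:02d}" for i in range(14)], 10)
        res = pairwise_posthoc(vals, labels)
        assert len(res) == 91

    def test_identical_pair_null(self):
        vals = np.r_[[0.2, 0.4, 0.6, 0.8], [0.2, 0.4, 0.6, 0.8]]
        labels = np.repeat(["a", "b"], 4)
        res = pairwise_posthoc(vals, labels)
        assert res[0].effect_size == pytest.approx(0.0, abs=1e-6)
        assert res[0].p_raw == pytest.approx(1.0, abs=1e-6)

    def test_effect_sign_and_magnitude(self):
        rng = np.random.default_rng(77)
        y1 = rng.beta(0.3 * 30, 0.7 * 30, 50)
        y2 = rng.beta(0.7 * 30, 0.3 * 30, 50)
        res = pairwise_posthoc(np.r_[y1, y2], np.repeat(["lo", "hi"], 50))
        assert res[0].site_a == "lo" and res[0].site_b == "hi"
        assert res[0].effect_size < 0
        assert res[0].effect_size_abs == pytest.approx(0.4, abs=0.08)
        assert res[0].significant

    def test_matches_general_fit_path(self):
        """The vectorized pair solver must agree with the general MLE route."""
        rng = np.random.default_rng(13)
        vals = rng.beta(4, 6, 30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = pairwise_posthoc(vals, labels)
        for r in res:
            m = np.isin(labels, [r.site_a, r.site_b])
            fit = fit_beta_groups(vals[m], labels[m])
            expect = fit.mean_of(r.site_a) - fit.mean_of(r.site_b)
            assert r.effect_size == pytest.approx(expect, abs=1e-5)


class TestHolm:
    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])
        np.testing.assert_allclose(holm_adjust([0.04]), [0.04])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        for m in (1, 3, 6, 20, 91):
            p = rng.uniform(0, 1, m)
            ours = holm_adjust(p)
            ref = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_exhaustive_permutations_small_m(self):
        """All permutations of m <= 6 inputs match the exhaustive
        max-over-prefix computation and are order-invariant."""
        base = np.array([0.001, 0.011, 0.02, 0.2, 0.24, 0.9])
        for m in range(1, 7):
            p = base[:m]
            sorted_adj = None
            for perm in itertools.permutations(range(m)):
                got = holm_adjust(p[list(perm)])
                # exhaustive oracle on the sorted p-values
                ps = np.sort(p)
                oracle = [min(1.0, max((m - j) * ps[j] for j in range(i + 1))) for i in range(m)]
                np.testing.assert_allclose(np.sort(got), oracle)
                if sorted_adj is None:
                    sorted_adj = np.sort(got)
                np.testing.assert_allclose(np.sort(got), sorted_adj)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_ties_preserved(self, p):
        p = np.array(p)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] == p[j]:
                    assert adj[i] == adj[j]
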