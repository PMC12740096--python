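import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mazetrait as mt
from mazetrait.io_formats import METRIC_NAMES, ValidationError


def table(cols, mice=None):
    mice = mice or [f"m{i:02d}" for i in range(len(next(iter(cols.values()))))]
    return pd.DataFrame(cols, index=pd.Index(mice, name="mouse_id"))


class TestZscore:
    def test_hand_computed_column(self):
        z = mt.zscore(table({"USS": [1.0, 2.0, 3.0]}))
        expected = [-1.2247448, 0.0, 1.2247448]  # population sd = sqrt(2/3)
        assert z["USS"].to_numpy() == pytest.approx(expected, abs=1e-6)

    def test_standardised_moments(self):
        rng = np.random.default_rng(0)
        df = table({"USS": rng.normal(5, 2, 30), "velocity": rng.gamma(4, 2, 30)})
        z = mt.zscore(df)
        for col in z:
            assert z[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_error_column_inverted(self):
        z = mt.zscore(table({"errors": [0.0, 2.0, 5.0]}))
        assert z["errors"].iloc[2] < z["errors"].iloc[0]  # more errors, lower Z
        assert z.attrs["inverted"] == ["errors"]

    def test_idempotent_on_complete_columns(self):
        rng = np.random.default_rng(1)
        df = table({"USS": rng.normal(size=20)})
        z1 = mt.zscore(df)
        z2 = mt.zscore(z1, invert=frozenset())
        pd.testing.assert_frame_equal(z1, z2, rtol=1e-12)

    def test_constant_column_names_metric(self):
        with pytest.raises(ValidationError, match="DMT"):
            mt.zscore(table({"DMT": [3.0, 3.0, 3.0]}))

    def test_sample_sd_switch(self):
        df = table({"USS": [1.0, 2.0, 3.0]})
        z_pop = mt.zscore(df)
        z_samp = mt.zscore(df, population_sd=False)
        ratio = z_samp["USS"].iloc[0] / z_pop["USS"].iloc[0]
        assert ratio == pytest.approx(math.sqrt(2 / 3))


class TestStouffer:
    def test_four_unit_scores(self):
        z = table({m: [1.0] for m in ["USS", "errors", "DMT", "OL1"]}, mice=["m00"])
        combined = mt.stouffer_combine(z, ["USS", "errors", "DMT", "OL1"])
        assert combined.iloc[0] == pytest.approx(2.0)

    def test_single_metric_identity(self):
        z = table({"USS": [0.3, -1.2, 0.9]})
        combined = mt.stouffer_combine(z, ["USS"])
        assert combined.to_numpy() == pytest.approx([0.3, -1.2, 0.9])

    def test_cancellation(self):
        z = table({"USS": [1.0], "DMT": [-1.0]}, mice=["m00"])
        assert mt.stouffer_combine(z, ["USS", "DMT"]).iloc[0] == pytest.approx(0.0)

    def test_missing_entries_reduce_k(self):
        z = table({"USS": [1.0, 1.0], "DMT": [1.0, np.nan]})
        combined = mt.stouffer_combine(z, ["USS", "DMT"])
        assert combined.iloc[0] == pytest.approx(2 / math.sqrt(2))
        assert combined.iloc[1] == pytest.approx(1.0)

    def test_standard_normal_output_for_independent_inputs(self):
        rng = np.random.default_rng(3)
        z = table({m: rng.normal(size=4000) for m in ["USS", "DMT", "errors"]},
                  mice=[f"m{i}" for i in range(4000)])
        combined = mt.stouffer_combine(z, ["USS", "DMT", "errors"])
        assert combined.mean() == pytest.approx(0.0, abs=0.05)
        assert combined.std(ddof=0) == pytest.approx(1.0, abs=0.05)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            mt.stouffer_combine(table({"USS": [0.0, 1.0]}), [])


class TestWeightedLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = mt.weighted_linear_fit(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_ridge_limit(self):
        x = np.arange(6.0)
        y = 3 * x - 2
        res = mt.weighted_linear_fit(x, y, ridge_lambda=1e9)
        assert res.slope == pytest.approx(0.0, abs=1e-6)
        assert res.intercept == pytest.approx(y.mean(), abs=1e-4)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5)
        y = 1.5 * x + rng.normal(size=5)
        res = mt.weighted_linear_fit(x, y)
        design = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert res.slope == pytest.approx(beta[0], abs=1e-10)
        assert res.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_penalised_solution_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = -0.7 * x + rng.normal(size=12)
        lam = 2.5
        res = mt.weighted_linear_fit(x, y, ridge_lambda=lam)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert res.slope == pytest.approx(sxy / (sxx + lam), abs=1e-12)

    def test_r_squared_equals_r_squared_of_pearson(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        res = mt.weighted_linear_fit(x, y)
        assert res.r_squared == pytest.approx(mt.pearson_r(x, y) ** 2, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            mt.weighted_linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_correlations(self):
        assert mt.pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert mt.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert mt.pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=5e-5)

    def test_brute_force_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert mt.pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_flagged(self, caplog):
        with caplog.at_level("WARNING", logger="mazetrait"):
            r = mt.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r)


class TestLifespanTrend:
    def test_constant_metric(self):
        res = mt.lifespan_trend([4, 8, 12, 18], [5.0, 5.0, 5.0, 5.0])
        assert res.slope == pytest.approx(0.0)
        assert math.isnan(res.r)

    def test_monotone_weight_series(self):
        res = mt.lifespan_trend([4, 8, 12, 18], [22.0, 24.1, 25.9, 28.5])
        assert res.r > 0.99
        assert res.p_value < 0.05

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(8)
        ages = np.repeat([4.0, 8.0, 12.0, 18.0], 16)
        planted = -0.5 / 4.667  # -0.5 sd per mean age step, in sd/month
        y = planted * ages + rng.normal(0, 0.3, len(ages))
        res = mt.lifespan_trend(ages, y)
        se = 0.3 / math.sqrt(np.sum((ages - ages.mean()) ** 2))
        assert res.slope == pytest.approx(planted, abs=3 * se)
        assert res.p_value < 0.05 and res.slope < 0

    def test_too_few_ages_missing(self):
        assert mt.lifespan_trend([4, 8], [1.0, 2.0]) is None


class TestPredictiveCorrelation:
    def test_identical_tables(self):
        rng = np.random.default_rng(9)
        z = table({"USS": rng.normal(size=10), "DMT": rng.normal(size=10)})
        res = mt.predictive_correlation(z, z.copy(), ["USS", "DMT"])
        assert res.r == pytest.approx(1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(10)
        z1 = table({"USS": rng.normal(size=500)})
        z2 = table({"USS": rng.normal(size=500)})
        res = mt.predictive_correlation(z1, z2, ["USS"])
        assert abs(res.r) < 3 / math.sqrt(500)

    def test_empty_subset_rejected(self):
        z = table({"USS": [0.0, 1.0, 2.0]})
        with pytest.raises(ValidationError):
            mt.predictive_correlation(z, z, [])


class TestCombinationSearch:
    @staticmethod
    def _ztables(metrics, n=20, seed=11):
        rng = np.random.default_rng(seed)
        mice = [f"m{i:02d}" for i in range(n)]
        out = {}
        for age in (4, 8, 12, 18):
            out[age] = table({m: rng.normal(size=n) for m in metrics}, mice=mice)
        return out

    def test_three_metric_universe_has_seven_subsets(self):
        zt = self._ztables(["USS", "DMT", "errors"])
        ranking = mt.combination_search(zt, ["USS", "DMT", "errors"])
        assert len(ranking) == 7
        assert ranking["metrics"].is_unique

    def test_exhaustive_and_unique(self):
        metrics = ["USS", "DMT", "errors", "OL1", "velocity"]
        ranking = mt.combination_search(self._ztables(metrics), metrics)
        assert len(ranking) == 2**5 - 1
        assert ranking["metrics"].is_unique
        assert (ranking["rank"] == np.arange(1, 32)).all()

    def test_planted_signal_ranks_top(self):
        rng = np.random.default_rng(12)
        n = 40
        mice = [f"m{i:02d}" for i in range(n)]
        g = rng.normal(size=n)
        stable = ["USS", "DMT", "errors"]
        noise_only = ["OL1", "OR1", "velocity"]
        zt = {}
        for age in (4, 8, 12, 18):
            cols = {m: g + 0.35 * rng.normal(size=n) for m in stable}
            cols.update({m: rng.normal(size=n) for m in noise_only})
            zt[age] = table(cols, mice=mice)
        ranking = mt.combination_search(zt, stable + noise_only)
        assert ranking.iloc[0]["metrics"] == "+".join(sorted(stable))


class TestResamplingVarianceCurve:
    def test_441_fits_for_21_mice(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=21)
        y = x + rng.normal(size=21)
        curve = mt.resampling_variance_curve(x, y, seed=0)
        assert curve.attrs["total_resamples"] == 441

    def test_full_sample_variance_zero(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        curve = mt.resampling_variance_curve(x, y, seed=1)
        full = curve.loc[curve["dof"] == 10, "variance"].iloc[0]
        assert full == pytest.approx(0.0, abs=1e-15)

    def test_variance_shrinks_at_high_dof(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=21)
        y = 0.7 * x + rng.normal(size=21) * 0.7
        curve = mt.resampling_variance_curve(x, y, n_resamples_per_size=60, seed=2)
        low = curve.loc[(curve["dof"] >= 1) & (curve["dof"] < 5), "variance"].mean()
        high = curve.loc[curve["dof"] > 10, "variance"].mean()
        assert high < low


class TestDetectDecliners:
    @staticmethod
    def _daily(slopes_by_metric, rng, ages=(4, 8, 12, 18), days=16):
        """One mouse's day-level tables from per-metric slopes (sd/month)."""
        out = {}
        for age in ages:
            data = {}
            for m in mt.MAZE_METRICS:
                drift = slopes_by_metric.get(m, 0.0) * (age - ages[0])
                data[m] = drift + rng.normal(0, 0.15, days)
            out[age] = pd.DataFrame(data)
        return out

    def test_one_adverse_metric_not_flagged(self):
        rng = np.random.default_rng(16)
        tables = {f"m{i:02d}": self._daily({}, rng) for i in range(8)}
        # mouse m07 declines in USS only
        tables["m07"] = self._daily({"USS": -0.5}, rng)
        flags = mt.detect_decliners(tables)
        assert not any(f.flagged for f in flags)
        m07 = next(f for f in flags if f.mouse_id == "m07")
        assert m07.n_adverse == 1

    def test_all_five_adverse_flagged(self):
        rng = np.random.default_rng(17)
        tables = {f"m{i:02d}": self._daily({}, rng) for i in range(8)}
        adverse = {
            "USS": -0.5, "errors": +0.5, "DMT": +0.5,
            "exploration_ratio": -0.5, "cumulative_arm_time": -0.5,
        }
        tables["m03"] = self._daily(adverse, rng)
        flags = mt.detect_decliners(tables)
        flagged = [f.mouse_id for f in flags if f.flagged]
        assert flagged == ["m03"]
        m03 = next(f for f in flags if f.mouse_id == "m03")
        assert m03.n_adverse >= 3
        assert all(p < 0.05 for p in m03.p_values.values())

    def test_favourable_trends_never_flag(self):
        rng = np.random.default_rng(18)
        tables = {f"m{i:02d}": self._daily({}, rng) for i in range(6)}
        improving = {"USS": +0.5, "errors": -0.5, "DMT": -0.5}
        tables["m01"] = self._daily(improving, rng)
        assert not any(f.flagged for f in mt.detect_decliners(tables))
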