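"""Comparison procedures: thresholds, difference bins, undercounts, cases."""

import numpy as np
import pandas as pd
import pytest

from himax.aggregation import daily_summaries
from himax.comparison import (
    compare_station,
    direct_compare,
    jja_threshold,
    nws_category_counts,
    report_frame,
    temporal_case_classify,
    underestimation_ratio,
)


def daily_frame(his24, hisest, dates=None, **extra):
    """Minimal daily-summary frame for arithmetic checks."""
    n = len(his24)
    if dates is None:
        dates = pd.date_range("2001-06-01", periods=n, freq="D")
    out = pd.DataFrame(
        {
            "date": pd.to_datetime(dates),
            "hismax24_f": np.asarray(his24, dtype=float),
            "hismaxest_f": np.asarray(hisest, dtype=float),
            "complete": np.ones(n, dtype=bool),
            "hour_tasmax": np.full(n, 14),
            "hour_hursmin": np.full(n, 14),
            "hour_hismax24": np.full(n, 14),
        }
    )
    for k, v in extra.items():
        out[k] = v
    return out


class TestJjaThreshold:
    def test_linear_interpolation_convention(self):
        # 100 JJA days spread over two summers so all of them enter
        dates = list(pd.date_range("2001-06-01", periods=50, freq="D")) + list(
            pd.date_range("2002-06-01", periods=50, freq="D")
        )
        days = daily_frame(np.arange(1.0, 101.0), np.arange(1.0, 101.0), dates=dates)
        assert jja_threshold(days).value_f == pytest.approx(95.05)

    def test_degenerate_distribution(self):
        days = daily_frame([85.0] * 10, [85.0] * 10)
        assert jja_threshold(days).value_f == pytest.approx(85.0)

    def test_matches_sort_and_interpolate_oracle(self, mixture_days):
        got = jja_threshold(mixture_days).value_f
        d = mixture_days[mixture_days["complete"]]
        vals = np.sort(
            d.loc[pd.DatetimeIndex(d["date"]).month.isin([6, 7, 8]), "hismax24_f"].to_numpy()
        )
        rank = 0.95 * (len(vals) - 1)
        lo, frac = int(np.floor(rank)), rank - int(np.floor(rank))
        oracle = vals[lo] + frac * (vals[lo + 1] - vals[lo])
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_only_complete_jja_days_enter(self):
        days = daily_frame([80.0, 200.0], [80.0, 200.0],
                           dates=["2001-06-01", "2001-06-02"])
        days.loc[1, "complete"] = False
        assert jja_threshold(days).value_f == pytest.approx(80.0)

    def test_period_restriction_and_empty_error(self):
        days = daily_frame([80.0] * 5, [80.0] * 5)
        with pytest.raises(ValueError):
            jja_threshold(days, period=(1990, 1991))


class TestDirectCompare:
    def test_coupled_noisefree_is_all_exact(self, coupled_noisefree_days):
        res = direct_compare(coupled_noisefree_days)
        assert res.exact_fraction == 1.0
        assert all(v == 0.0 for k, v in res.bin_fractions.items() if k != "0")

    def test_bin_arithmetic(self):
        days = daily_frame([90.0, 95.0], [89.5, 91.5])
        res = direct_compare(days)
        assert res.exact_fraction == 0.0
        assert res.bin_fractions["(0,1]"] == pytest.approx(0.5)
        assert res.bin_fractions[">3"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, mixture_days):
        res = direct_compare(mixture_days)
        assert sum(res.bin_fractions.values()) == pytest.approx(1.0)

    def test_only_heat_season_days_counted(self):
        days = daily_frame([90.0, 90.0], [90.0, 85.0],
                           dates=["2001-07-01", "2001-12-01"])
        res = direct_compare(days)
        assert res.n_days == 1
        assert res.exact_fraction == 1.0

    def test_bin_mass_shifts_with_surge_amplitude(self):
        from himax.synthetic_weather import RegimeSpec, SyntheticStationConfig, simulate_station

        heavy_mass = []
        for amp in (2.0, 8.0, 14.0):
            cfg = SyntheticStationConfig(
                n_years=1, tmin_mean=14.0, tmax_mean=23.0,
                noise_sd=0.0, td_noise_sd=0.0, synoptic_sd=0.0, missing_rate=0.0,
                regimes=(RegimeSpec("surge", surge_amplitude=amp),),
                regime_probs=(1.0,), dewpoint_depression=6.0, seed=17,
            )
            res = direct_compare(daily_summaries(simulate_station(cfg)))
            heavy_mass.append(res.bin_fractions["(1,2]"]
                              + res.bin_fractions["(2,3]"]
                              + res.bin_fractions[">3"])
        assert heavy_mass[0] <= heavy_mass[1] <= heavy_mass[2]


class TestUnderestimationRatio:
    def test_identical_series_gives_zero(self):
        days = daily_frame([90.0, 95.0, 100.0], [90.0, 95.0, 100.0])
        assert underestimation_ratio(days, 92.0).ratio == 0.0

    def test_ratio_arithmetic(self):
        his24 = np.concatenate([np.full(100, 101.0), np.full(50, 90.0)])
        hisest = np.concatenate([np.full(37, 101.0), np.full(63, 99.0), np.full(50, 90.0)])
        days = daily_frame(his24, hisest,
                           dates=pd.date_range("2001-01-01", periods=150, freq="D"))
        res = underestimation_ratio(days, 100.0)
        assert res.n24_extreme_days == 100
        assert res.nest_extreme_days == 37
        assert res.ratio == pytest.approx(0.63)

    def test_membership_is_strict_exceedance(self):
        days = daily_frame([100.0], [100.0])
        res = underestimation_ratio(days, 100.0)
        assert res.n24_extreme_days == 0
        assert np.isnan(res.ratio)

    def test_estimate_extremes_subset_of_true_extremes(self, mixture_days):
        d = mixture_days[mixture_days["complete"]]
        for thr in np.arange(70.0, 110.0, 5.0):
            est = d["hismaxest_f"] > thr
            true = d["hismax24_f"] > thr
            assert not (est & ~true).any()


class TestCategoryCounts:
    @pytest.mark.parametrize(
        "value, category",
        [
            (80.0, "Caution"),
            (89.99, "Caution"),
            (90.0, "Extreme Caution"),
            (103.0, "Danger"),
            (124.99, "Danger"),
            (125.0, "Extreme Danger"),
        ],
    )
    def test_half_open_interval_classification(self, value, category):
        counts = nws_category_counts([value])
        assert counts[category] == 1
        assert sum(counts.values()) == 1

    def test_below_caution_floor_uncounted(self):
        assert sum(nws_category_counts([79.99, 60.0]).values()) == 0

    def test_top_categories_never_overcounted_by_estimate(self, mixture_days):
        d = mixture_days[mixture_days["complete"]]
        c24 = nws_category_counts(d["hismax24_f"])
        cest = nws_category_counts(d["hismaxest_f"])
        top24 = c24["Danger"] + c24["Extreme Danger"]
        topest = cest["Danger"] + cest["Extreme Danger"]
        assert topest <= top24


class TestTemporalCases:
    def test_constant_day_is_case_1(self, hourly_frame):
        df = hourly_frame(range(24), [32.2] * 24, [50.0] * 24)
        days = daily_summaries(df)
        assert temporal_case_classify(days)[0] == 1

    def test_humid_afternoon_is_case_2(self, hourly_frame):
        # RH at the T peak exceeds the daily minimum, yet HI still peaks
        # with the temperature: hot enough that T dominates.
        df = hourly_frame([10, 14], [25.0, 36.0], [20.0, 40.0])
        days = daily_summaries(df, min_valid_hours=2)
        day = days.iloc[0]
        assert day["hour_tasmax"] == 14 and day["hour_hursmin"] == 10
        assert day["hour_hismax24"] == 14
        assert temporal_case_classify(days)[0] == 2

    def test_evening_surge_day_is_case_3(self, surge_days):
        cases = temporal_case_classify(surge_days)
        assert (cases == 3).any()

    def test_case1_with_warm_hours_implies_exact_match(self, surge_days):
        cases = temporal_case_classify(surge_days)
        case1 = surge_days[(cases == 1)]
        warm = case1[case1["tasmax_c"] > 10.0]
        assert np.allclose(warm["hismaxest_f"], warm["hismax24_f"], atol=1e-6)


class TestReport:
    def test_full_report_assembly(self, mixture_days):
        rep = compare_station(mixture_days, station="SYN")
        assert sum(rep.case_fractions.values()) == pytest.approx(1.0)
        assert 0.0 <= rep.underestimation.ratio <= 1.0
        frame = report_frame({"SYN": rep})
        assert frame.shape[0] == 1
        assert frame["exact_match_fraction"].iloc[0] == rep.direct.exact_fraction
        assert {"station", "jja_p95_hismax24_f", "underestimation_ratio"} <= set(frame.columns)
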