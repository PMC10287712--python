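"""Chilling-unit computation, preprocessing and grid enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chillqy import (
    CUConfig,
    GridSpec,
    ThresholdRange,
    WindowRange,
    compute_cu,
    enumerate_grid,
    filter_by_missing_rate,
    impute_missing,
    period_max_cu,
)
from _oracles import brute_cu, make_series


class TestMissingRateFilter:
    def test_boundary_rate_is_accepted(self):
        vals = [10.0] * 90 + [np.nan] * 10
        decision = filter_by_missing_rate(make_series(tavg=vals), "avg", 0.10)
        assert decision.accepted and decision.missing_rate == pytest.approx(0.10)

    def test_just_over_boundary_is_rejected(self):
        vals = [10.0] * 89 + [np.nan] * 11
        assert not filter_by_missing_rate(make_series(tavg=vals), "avg", 0.10).accepted

    def test_complete_record_has_rate_zero(self):
        decision = filter_by_missing_rate(make_series(tavg=[1.0, 2.0, 3.0]), "avg")
        assert decision.accepted and decision.missing_rate == 0.0

    def test_empty_series_rejected(self):
        empty = make_series(tavg=[1.0])
        empty.frame = empty.frame.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            filter_by_missing_rate(empty, "avg")


class TestImputation:
    def test_single_gap_gets_neighbour_mean(self):
        s = make_series(tmax=[5, np.nan, 7], tmin=[0, 0, 0], tavg=[2, 2, 2])
        out = impute_missing(s)
        assert out.frame["tmax"].tolist() == [5.0, 6.0, 7.0]

    def test_run_of_gaps_gets_linear_interpolation(self):
        s = make_series(
            tmax=[4, np.nan, np.nan, 10], tmin=[0] * 4, tavg=[2] * 4
        )
        assert impute_missing(s).frame["tmax"].tolist() == [4.0, 6.0, 8.0, 10.0]

    def test_complete_series_unchanged(self):
        s = make_series(tavg=[3.0, 4.0, 5.0])
        pd.testing.assert_frame_equal(impute_missing(s).frame, s.frame)

    def test_boundary_gap_rejected_with_date(self):
        s = make_series(tmax=[np.nan, 5, 7], tmin=[0] * 3, tavg=[2] * 3)
        with pytest.raises(ValueError, match="2020-01-01"):
            impute_missing(s)

    def test_observed_values_preserved_exactly(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(10, 5, 50)
        gappy = vals.copy()
        gappy[rng.choice(np.arange(1, 49), 10, replace=False)] = np.nan
        out = impute_missing(make_series(tavg=gappy))
        keep = ~np.isnan(gappy)
        np.testing.assert_array_equal(out.frame["tavg"].to_numpy()[keep], vals[keep])


class TestComputeCU:
    def test_day_count_hand_example(self):
        s = make_series(tmax=[10, 9, 8, 10, 9])
        cu = compute_cu(s, CUConfig("day_count", "max", 9.5, 5))
        assert cu.values.tolist() == [3.0]

    @pytest.mark.parametrize("cu_type", ["day_count", "temperature_sum"])
    def test_threshold_below_everything_gives_zero(self, cu_type):
        s = make_series(tavg=[5.0, 6.0, 7.0, 8.0])
        cu = compute_cu(s, CUConfig(cu_type, "avg", -10.0, 2))
        assert (cu.values == 0).all()

    def test_temperature_sum_is_the_deficit(self):
        s = make_series(tavg=[5.0, 6.0])
        cu = compute_cu(s, CUConfig("temperature_sum", "avg", 7.0, 2))
        assert cu.values.tolist() == [3.0]

    def test_raw_sum_variant(self):
        s = make_series(tavg=[5.0, 6.0])
        cu = compute_cu(
            s, CUConfig("temperature_sum", "avg", 7.0, 2), temperature_sum_kind="raw"
        )
        assert cu.values.tolist() == [11.0]

    def test_short_series_yields_no_dates(self):
        s = make_series(tavg=[5.0, 6.0])
        assert compute_cu(s, CUConfig("day_count", "avg", 7.0, 5)).values.empty

    def test_missing_values_rejected(self):
        s = make_series(tavg=[5.0, np.nan, 6.0])
        with pytest.raises(ValueError, match="impute"):
            compute_cu(s, CUConfig("day_count", "avg", 7.0, 2))

    @pytest.mark.parametrize("cu_type", ["day_count", "temperature_sum"])
    @pytest.mark.parametrize("stat", ["max", "min", "avg"])
    def test_matches_brute_force(self, cu_type, stat):
        rng = np.random.default_rng(11)
        vals = rng.normal(8, 6, 30)
        s = make_series(tmax=vals + 5, tmin=vals - 5, tavg=vals)
        for th, L in [(5.0, 3), (9.5, 7), (0.0, 1)]:
            got = compute_cu(s, CUConfig(cu_type, stat, th, L)).values.to_numpy()
            want = brute_cu(s.stat(stat).to_numpy(), cu_type, th, L)
            np.testing.assert_allclose(got, want)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        temps=st.lists(
            st.floats(-15, 25, allow_nan=False), min_size=8, max_size=25
        ),
        th=st.floats(-5, 15),
        L=st.integers(1, 8),
        cu_type=st.sampled_from(["day_count", "temperature_sum"]),
    )
    def test_monotone_in_threshold_and_window(self, temps, th, L, cu_type):
        s = make_series(tavg=temps)
        base = compute_cu(s, CUConfig(cu_type, "avg", th, L)).values
        hotter = compute_cu(s, CUConfig(cu_type, "avg", th + 1.5, L)).values
        assert (hotter >= base).all()
        if L + 1 <= len(temps):
            longer = compute_cu(s, CUConfig(cu_type, "avg", th, L + 1)).values
            assert (longer.to_numpy() >= base.to_numpy()[1:]).all()
        if cu_type == "day_count":
            assert (base <= L).all()
            assert (base == base.round()).all()

    def test_day_count_translation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 4, 20)
        c = 7.3
        a = compute_cu(make_series(tavg=vals), CUConfig("day_count", "avg", 6.0, 4))
        b = compute_cu(
            make_series(tavg=vals + c), CUConfig("day_count", "avg", 6.0 + c, 4)
        )
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())


class TestGridSpec:
    def test_default_counts(self):
        spec = GridSpec()
        assert len(spec.threshold_grid("max")) == 61
        assert len(spec.window_grid()) == 70
        assert spec.n_configs == 25_620

    def test_enumeration_order_is_type_stat_threshold_window(self):
        spec = GridSpec.reduced([1.0, 2.0], [3, 4], cu_types=("day_count",),
                                temp_stats=("max",))
        configs = enumerate_grid(spec)
        assert [(c.threshold, c.window) for c in configs] == [
            (1.0, 3), (1.0, 4), (2.0, 3), (2.0, 4)
        ]

    def test_collapsed_grid_gives_six_configs(self):
        spec = GridSpec.reduced([5.0], [1])
        assert len(enumerate_grid(spec)) == 6

    def test_step_not_dividing_range_rejected(self):
        with pytest.raises(ValueError, match="does not divide"):
            ThresholdRange(0.0, 1.0, 0.3).grid()
        with pytest.raises(ValueError, match="does not divide"):
            WindowRange(1, 10, 4).grid()

    def test_default_thresholds_bracket_selected_optima(self):
        spec = GridSpec()
        for stat, opt in [("max", 9.5), ("max", 11.0), ("avg", 5.0),
                          ("avg", 2.75), ("min", -1.25), ("min", -4.0)]:
            grid = spec.threshold_grid(stat)
            assert np.isclose(grid, opt).any()


class TestPeriodMax:
    def test_max_by_inspection(self):
        s = make_series(tavg=list(range(10)))
        cu = compute_cu(s, CUConfig("day_count", "avg", 100.0, 1))
        cu.values[:] = [0, 3, 35, 12, 1, 1, 1, 1, 1, 1]
        assert period_max_cu(cu, (s.dates[0], s.dates[3])) == 35

    def test_constant_series(self):
        s = make_series(tavg=[1.0] * 5)
        cu = compute_cu(s, CUConfig("day_count", "avg", 2.0, 1))
        assert period_max_cu(cu, (s.dates[0], s.dates[-1])) == 1.0

    def test_warm_site_never_below_threshold(self):
        s = make_series(tavg=[25.0] * 8)
        cu = compute_cu(s, CUConfig("day_count", "avg", 9.5, 3))
        assert period_max_cu(cu, (s.dates[0], s.dates[-1])) == 0.0

    def test_empty_overlap_rejected(self):
        s = make_series(tavg=[1.0] * 5)
        cu = compute_cu(s, CUConfig("day_count", "avg", 2.0, 1))
        with pytest.raises(ValueError, match="no CU values"):
            period_max_cu(cu, (pd.Timestamp("1999-01-01"), pd.Timestamp("1999-02-01")))
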