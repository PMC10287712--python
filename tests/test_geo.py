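"""Site reduction, SVM interpolation and suitability classification."""

import numpy as np
import pandas as pd
import pytest

from chillqy import (
    CUConfig,
    ClimateParams,
    SiteRecord,
    classify_suitability,
    gen_temperature_series,
    network_period_max_cu,
    site_period_max_cu,
    svm_interpolate,
)
from _oracles import brute_cu, make_series

CFG = CUConfig("day_count", "max", 9.5, 46)


def constant_site(site_id, lat, lon, tmax_level, n_days=200):
    params = ClimateParams(
        annual_mean=tmax_level - 4.5, seasonal_amplitude=0.0, daily_noise_sd=0.0,
        diurnal_half_range=4.5, seed=0,
    )
    series = gen_temperature_series(params, "2020-01-01", n_days, site_id=site_id)
    return SiteRecord(site_id, lat, lon, series)


class TestSitePeriodMax:
    def test_tropical_site_accumulates_nothing(self):
        site = constant_site("trop", 5, 100, tmax_level=30.0)
        period = (site.series.dates[50], site.series.dates[-1])
        assert site_period_max_cu(site, CFG, period) == 0.0

    def test_polar_site_saturates_at_window(self):
        site = constant_site("polar", 70, 100, tmax_level=-5.0)
        period = (site.series.dates[50], site.series.dates[-1])
        assert site_period_max_cu(site, CFG, period) == CFG.window

    def test_midlatitude_site_matches_brute_force(self):
        rng = np.random.default_rng(17)
        tmax = rng.normal(9.5, 3.0, 150)
        series = make_series(tmax=tmax, tmin=tmax - 9, tavg=tmax - 4.5)
        site = SiteRecord("mid", 36, 140, series)
        period = (series.dates[60], series.dates[-1])
        got = site_period_max_cu(site, CFG, period)
        brute = brute_cu(tmax, "day_count", 9.5, 46)
        idx = pd.date_range(series.dates[45], periods=len(brute), freq="D")
        want = pd.Series(brute, index=idx).loc[period[0]:period[1]].max()
        assert got == want
        assert 0 < got < CFG.window

    def test_gappy_site_excluded_with_reason(self):
        site = constant_site("gap", 40, 100, tmax_level=5.0)
        site.series.frame.iloc[10:60] = np.nan
        with pytest.raises(ValueError, match="missing rate"):
            site_period_max_cu(site, CFG, (site.series.dates[50],
                                           site.series.dates[-1]))

    def test_short_record_excluded(self):
        site = constant_site("short", 40, 100, tmax_level=5.0, n_days=30)
        with pytest.raises(ValueError, match="shorter than window"):
            site_period_max_cu(site, CFG, (site.series.dates[0],
                                           site.series.dates[-1]))

    def test_network_output_invariant_to_site_order(self):
        sites = [constant_site(f"s{i}", 10 + i * 5, 100, tmax_level=5 + 3 * i)
                 for i in range(5)]
        period = (sites[0].series.dates[50], sites[0].series.dates[-1])
        fwd, _ = network_period_max_cu(sites, CFG, period)
        rev, _ = network_period_max_cu(sites[::-1], CFG, period)
        merged = fwd.merge(rev, on="site_id", suffixes=("_f", "_r"))
        assert (merged["value_f"] == merged["value_r"]).all()


def lattice_sites(values_fn, lats=np.arange(20, 51, 2.0), lons=(100.0, 110.0, 120.0)):
    rows = []
    for la in lats:
        for lo in lons:
            rows.append((la, lo, values_fn(la)))
    return pd.DataFrame(rows, columns=["lat", "lon", "value"])


class TestSVMInterpolate:
    def test_constant_field_predicts_the_constant(self):
        sites = lattice_sites(lambda lat: 12.0)
        grid = svm_interpolate(sites, 2.0, "regression")
        assert np.allclose(grid.cells["value"], 12.0, atol=1e-3)

    def test_grid_arithmetic(self):
        sites = pd.DataFrame({
            "lat": np.linspace(0, 4, 10), "lon": np.linspace(0, 4, 10),
            "value": np.linspace(0, 1, 10),
        })
        grid = svm_interpolate(sites, 2.0, "regression", bounding_box=(0, 4, 0, 4))
        assert len(grid.cells) == 9

    def test_training_predictions_track_smooth_field(self):
        sites = lattice_sites(lambda lat: 46 / (1 + np.exp(-(lat - 35) / 4)))
        grid = svm_interpolate(sites, 2.0, "regression")
        r = np.corrcoef(grid.training_predictions["predicted"], sites["value"])[0, 1]
        assert r > 0.9

    def test_classification_boundary_near_true_latitude(self):
        sites = lattice_sites(lambda lat: lat)
        sites["suitable"] = sites["lat"] < 35
        grid = svm_interpolate(sites, 0.5, "classification")
        cells = grid.cells
        northmost = cells[cells["suitable"]].groupby("lon")["lat"].max()
        assert (abs(northmost - 35.0) <= 1.0).all()

    def test_single_class_rejected(self):
        sites = lattice_sites(lambda lat: lat)
        sites["suitable"] = True
        with pytest.raises(ValueError, match="both classes"):
            svm_interpolate(sites, 2.0, "classification")

    def test_too_few_sites_rejected(self):
        sites = lattice_sites(lambda lat: lat, lats=[20.0], lons=[100.0])
        with pytest.raises(ValueError, match="at least 10"):
            svm_interpolate(sites, 2.0, "regression")

    def test_deterministic_for_fixed_inputs(self):
        sites = lattice_sites(lambda lat: 46 / (1 + np.exp(-(lat - 35) / 4)))
        a = svm_interpolate(sites, 2.0, "regression")
        b = svm_interpolate(sites, 2.0, "regression")
        pd.testing.assert_frame_equal(a.cells, b.cells)


class TestClassifySuitability:
    def grid_from(self, values):
        sites = lattice_sites(lambda lat: lat)
        g = svm_interpolate(sites, 2.0, "regression")
        g.cells = pd.DataFrame({"lat": np.zeros(len(values)),
                                "lon": np.arange(len(values), dtype=float),
                                "value": values})
        return g

    def test_cu_threshold_boundary_inclusive(self):
        g = self.grid_from([10.0, 35.0, 40.0])
        out, count = classify_suitability(g, 35.0, "cu_max")
        assert out.cells["suitable"].tolist() == [True, True, False]
        assert count == 2

    def test_qy_kind_thresholds_upward(self):
        g = self.grid_from([0.1, 0.3])
        out, count = classify_suitability(g, 0.2, "qy_min")
        assert out.cells["suitable"].tolist() == [False, True]
        assert count == 1

    def test_empty_grid_counts_zero(self):
        g = self.grid_from([])
        _, count = classify_suitability(g, 35.0, "cu_max")
        assert count == 0

    def test_count_monotone_in_cu_threshold(self):
        rng = np.random.default_rng(23)
        g = self.grid_from(rng.uniform(0, 46, 50))
        counts = [classify_suitability(g, th, "cu_max")[1]
                  for th in np.linspace(0, 46, 12)]
        assert (np.diff(counts) >= 0).all()

    def test_nonfinite_threshold_rejected(self):
        g = self.grid_from([1.0])
        with pytest.raises(ValueError, match="finite"):
            classify_suitability(g, np.inf, "cu_max")
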