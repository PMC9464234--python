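"""Monte-Carlo binning, gridding, composites, seasonality, trends."""

import numpy as np
import pandas as pd
import pytest

from pollenrecon.stacking import (
    composite,
    default_bins,
    fit_trend,
    grid_average,
    seasonality,
    to_binned,
)
from pollenrecon.types import BinnedSeries, ReconSeries, Site, ValidationError


def _recon(ages, values, errors=None, lat=50.0, lon=10.0):
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    errors = np.zeros_like(values) if errors is None else np.asarray(errors, float)
    table = pd.DataFrame({"age": ages, "mtco": values, "mtco_error": errors})
    return ReconSeries(site=Site(site_id=f"s{lat}_{lon}", lat=lat, lon=lon),
                       table=table)


def _series(site, anomaly, se=None, centers=None):
    centers = default_bins() if centers is None else centers
    anomaly = np.asarray(anomaly, float)
    se = np.zeros_like(anomaly) if se is None else np.asarray(se, float)
    n = np.where(np.isnan(anomaly), 0, 1)
    return BinnedSeries(site=site, variable="mtco", bin_centers=centers,
                        anomaly=anomaly, bin_se=se, bin_sem=se, n_contributing=n)


class TestToBinned:
    def test_noiseless_samples_on_bin_centers(self):
        centers = default_bins()
        ages = centers.copy()
        values = 0.001 * ages
        b = to_binned(_recon(ages, values), "mtco", n_mc=50, seed=0)
        ref_mean = values[ages <= 1000.0].mean()
        np.testing.assert_allclose(b.anomaly, values - ref_mean, atol=1e-9)
        np.testing.assert_allclose(b.bin_se, 0.0, atol=1e-12)

    def test_constant_series_zero_anomaly(self):
        ages = np.linspace(100.0, 10900.0, 30)
        b = to_binned(_recon(ages, np.full(30, -7.0)), "mtco", n_mc=20, seed=1)
        cov = ~np.isnan(b.anomaly)
        np.testing.assert_allclose(b.anomaly[cov], 0.0, atol=1e-12)

    def test_binned_median_tracks_noiseless_interpolation(self):
        ages = np.linspace(150.0, 10800.0, 40)
        values = np.sin(ages / 1500.0)
        errors = np.full(40, 0.3)
        b = to_binned(_recon(ages, values, errors), "mtco", n_mc=400, seed=2)
        ref = np.interp(b.bin_centers, ages, values - values[ages <= 1000].mean())
        cov = ~np.isnan(b.anomaly)
        assert np.all(np.abs(b.anomaly[cov] - ref[cov]) <= 2.5 * b.bin_se[cov]
                      / np.sqrt(1) + 0.1)

    def test_missing_reference_window_errors(self):
        ages = np.linspace(3000.0, 9000.0, 10)
        with pytest.raises(ValidationError, match="reference"):
            to_binned(_recon(ages, np.zeros(10)), "mtco", n_mc=10, seed=0)

    def test_uncovered_bins_missing_not_zero(self):
        ages = np.linspace(100.0, 6000.0, 20)
        b = to_binned(_recon(ages, np.zeros(20)), "mtco", n_mc=10, seed=3)
        assert np.isnan(b.anomaly[b.bin_centers > 6000.0]).all()


class TestGridAverage:
    def test_one_site_per_cell_identity(self):
        s1 = _series(Site(site_id="a", lat=50.5, lon=10.5), np.ones(55))
        s2 = _series(Site(site_id="b", lat=60.5, lon=20.5), np.zeros(55))
        cells = grid_average([s1, s2])
        assert cells.anomaly.shape[0] == 2
        assert set(np.unique(cells.anomaly)) == {0.0, 1.0}

    def test_two_sites_in_cell_average_to_zero(self):
        s1 = _series(Site(site_id="a", lat=50.2, lon=10.2), np.full(55, 1.0))
        s2 = _series(Site(site_id="b", lat=50.8, lon=10.8), np.full(55, -1.0))
        cells = grid_average([s1, s2])
        np.testing.assert_allclose(cells.anomaly, 0.0, atol=1e-12)

    def test_edge_site_goes_to_higher_cell(self):
        # lat 52 with 2-deg cells is the lower edge of [52, 54)
        s = _series(Site(site_id="e", lat=52.0, lon=10.0), np.ones(55))
        cells = grid_average([s])
        assert cells.cell_lat[0] == pytest.approx(53.0)

    def test_site_order_invariance(self):
        sites = [Site(site_id=f"s{i}", lat=48.0 + i, lon=5.0 + i) for i in range(4)]
        rng = np.random.default_rng(0)
        series = [_series(s, rng.normal(size=55)) for s in sites]
        a = grid_average(series)
        b = grid_average(series[::-1])
        np.testing.assert_allclose(a.anomaly, b.anomaly, atol=1e-12)


class TestComposite:
    def test_single_cell_zero_error(self):
        s = _series(Site(site_id="a", lat=50.5, lon=10.5),
                    np.linspace(-1, 1, 55))
        cells = grid_average([s])
        comp = composite(cells, n_mc=100, seed=0)
        np.testing.assert_allclose(comp["median"], s.anomaly, atol=1e-12)
        np.testing.assert_allclose(comp["upper95"] - comp["lower95"], 0.0,
                                   atol=1e-12)

    def test_band_width_scales_with_cells(self):
        """Half-width ~ 1.96 sigma / sqrt(n) for iid cell noise."""
        rng = np.random.default_rng(5)
        sigma, n_cells = 1.0, 25
        series = []
        for i in range(n_cells):
            site = Site(site_id=f"c{i}", lat=30.0 + 2 * (i % 5) + 0.5,
                        lon=2 * (i // 5) + 0.5)
            series.append(_series(site, np.zeros(55), se=np.full(55, sigma)))
        comp = composite(grid_average(series), n_mc=2000, seed=6)
        half = ((comp["upper95"] - comp["lower95"]) / 2).mean()
        assert half == pytest.approx(1.96 * sigma / np.sqrt(n_cells), rel=0.12)

    def test_empty_region_filter_errors(self):
        s = _series(Site(site_id="a", lat=50.5, lon=10.5), np.ones(55))
        with pytest.raises(ValidationError):
            composite(grid_average([s]), n_mc=10, seed=0, region="W_NA")

    def test_region_filter_selects_cells(self):
        eu = _series(Site(site_id="eu", lat=50.5, lon=10.5), np.ones(55))
        na = _series(Site(site_id="na", lat=50.5, lon=-120.5), np.zeros(55))
        comp = composite(grid_average([eu, na]), n_mc=10, seed=0, region="NE_EU")
        np.testing.assert_allclose(comp["median"], 1.0, atol=1e-12)


class TestSeasonalityAndTrend:
    def _comp(self, medians, halfwidth=0.0):
        n = len(medians)
        return pd.DataFrame({"bin_center": default_bins()[:n],
                             "median": np.asarray(medians, float),
                             "lower95": np.asarray(medians, float) - halfwidth,
                             "upper95": np.asarray(medians, float) + halfwidth,
                             "n_cells": np.ones(n, dtype=int)})

    def test_identical_curves_zero_seasonality(self):
        c = self._comp(np.sin(np.arange(10.0)))
        s = seasonality(c, c)
        np.testing.assert_allclose(s["median"], 0.0, atol=1e-12)

    def test_winter_warming_reduces_seasonality(self):
        ages = default_bins()[:20]
        summer = self._comp(np.zeros(20))
        winter = self._comp((ages.max() - ages) / (ages.max() - ages.min()))
        s = seasonality(summer, winter)
        # winter warms 1 deg C toward present -> seasonality falls 1 deg C
        assert s["median"].iloc[0] - s["median"].iloc[-1] == pytest.approx(-1.0)

    def test_elementwise_subtraction_and_quadrature_band(self):
        a = self._comp([1.0, 2.0, 3.0], halfwidth=0.3)
        b = self._comp([0.5, 1.0, 1.5], halfwidth=0.4)
        s = seasonality(a, b)
        np.testing.assert_allclose(s["median"], [0.5, 1.0, 1.5])
        np.testing.assert_allclose((s["upper95"] - s["lower95"]) / 2, 0.5)

    def test_misaligned_bins_error(self):
        a = self._comp([1.0, 2.0])
        b = self._comp([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            seasonality(a, b)

    def test_linear_trend_recovered_exactly(self):
        ages_ka = default_bins()[:30] / 1000.0
        # 0.5 deg C per ka warming toward the present
        comp = self._comp(-0.5 * ages_ka)
        rate, se = fit_trend(comp, (0.0, 6.0))
        assert rate == pytest.approx(0.5, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_curve_zero_trend(self):
        comp = self._comp(np.full(20, 2.0))
        assert fit_trend(comp, (0.0, 4.0))[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_bins_error(self):
        comp = self._comp([1.0, 2.0])
        with pytest.raises(ValidationError):
            fit_trend(comp, (0.0, 0.4))
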