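"""Radiocarbon calibration, age-depth models and screening rules."""

import numpy as np
import pytest

from pollenrecon.chronology import (
    assign_site_climate,
    build_age_model,
    calibrate_c14,
    screen_record,
    screen_samples,
)
from pollenrecon.synthetic import make_calib_curve, make_climate_field
from pollenrecon.types import (
    AgeControl,
    AgeModel,
    CalibCurve,
    FossilRecord,
    PollenCounts,
    Site,
    ValidationError,
)


def _identity_curve():
    return make_calib_curve("identity")


class TestCalibrateC14:
    def test_identity_curve(self):
        res = calibrate_c14(5000.0, 50.0, _identity_curve())
        assert res.point_age == pytest.approx(5000.0, abs=0.5)
        assert res.age_sd == pytest.approx(50.0, rel=0.02)

    def test_linear_curve_inversion(self):
        res = calibrate_c14(4500.0, 45.0, make_calib_curve("linear"))
        assert res.point_age == pytest.approx(5000.0, abs=1.0)

    def test_wiggly_curve_matches_dense_quadrature(self):
        """Posterior mean agrees with brute-force quadrature on a 1-yr grid."""
        curve = make_calib_curve("wiggly")
        age14, sig = 4700.0, 60.0
        res = calibrate_c14(age14, sig, curve)
        theta = np.arange(0.0, 13000.0, 1.0)
        mu = np.interp(theta, curve.cal_age, curve.c14_age)
        s = np.sqrt(sig**2 + np.interp(theta, curve.cal_age, curve.curve_sigma) ** 2)
        dens = np.exp(-0.5 * ((age14 - mu) / s) ** 2) / s
        dens /= np.trapezoid(dens, theta)
        oracle_mean = np.trapezoid(dens * theta, theta)
        assert res.point_age == pytest.approx(oracle_mean, abs=0.1)

    def test_posterior_normalized(self):
        res = calibrate_c14(3000.0, 40.0, make_calib_curve("wiggly"))
        assert np.trapezoid(res.density, res.cal_grid) == pytest.approx(1.0, abs=1e-9)

    def test_translation_equivariance(self):
        """A constant-offset curve shifts the point age by exactly that offset."""
        base = make_calib_curve("wiggly")
        shifted = CalibCurve(cal_age=base.cal_age, c14_age=base.c14_age + 200.0,
                             curve_sigma=base.curve_sigma)
        a = calibrate_c14(4700.0, 60.0, base)
        b = calibrate_c14(4900.0, 60.0, shifted)
        assert b.point_age == pytest.approx(a.point_age, abs=1e-6)

    def test_out_of_support_errors(self):
        with pytest.raises(ValidationError):
            calibrate_c14(50000.0, 30.0, _identity_curve())
        with pytest.raises(ValidationError):
            calibrate_c14(1000.0, -5.0, _identity_curve())


class TestAgeModel:
    def test_midpoint_interpolation(self):
        controls = [AgeControl(depth=0.0, kind="calendar", age=0.0),
                    AgeControl(depth=100.0, kind="calendar", age=10000.0)]
        model = build_age_model(controls, np.array([50.0]))
        assert model.sample_ages[0] == pytest.approx(5000.0)
        assert model.flags == ["interpolated"]

    def test_sample_at_control_depth_is_direct(self):
        controls = [AgeControl(depth=0.0, kind="calendar", age=0.0),
                    AgeControl(depth=100.0, kind="calendar", age=10000.0)]
        model = build_age_model(controls, np.array([100.0]))
        assert model.sample_ages[0] == pytest.approx(10000.0)
        assert model.flags == ["direct"]

    def test_three_controls_hand_oracle(self):
        controls = [AgeControl(depth=0.0, kind="calendar", age=100.0),
                    AgeControl(depth=40.0, kind="calendar", age=3000.0),
                    AgeControl(depth=100.0, kind="calendar", age=9600.0)]
        model = build_age_model(controls, np.array([70.0]))
        # hand interpolation between (40, 3000) and (100, 9600)
        expected = 3000.0 + (9600.0 - 3000.0) * (70.0 - 40.0) / 60.0
        assert model.sample_ages[0] == pytest.approx(expected)

    def test_reversal_rejected_with_pair_named(self):
        controls = [AgeControl(depth=0.0, kind="calendar", age=5000.0),
                    AgeControl(depth=50.0, kind="calendar", age=2000.0)]
        with pytest.raises(ValidationError, match="reversal"):
            build_age_model(controls, np.array([10.0]))

    def test_too_few_controls(self):
        with pytest.raises(ValidationError):
            build_age_model([AgeControl(depth=0.0, kind="calendar", age=0.0)],
                            np.array([1.0]))

    def test_extrapolation_flagged(self):
        controls = [AgeControl(depth=10.0, kind="calendar", age=1000.0),
                    AgeControl(depth=20.0, kind="calendar", age=2000.0)]
        model = build_age_model(controls, np.array([5.0, 30.0]))
        assert model.flags == ["extrapolated", "extrapolated"]
        assert model.sample_ages[0] == pytest.approx(500.0)


def _model(sample_ages, control_ages, depths=None):
    sample_ages = np.asarray(sample_ages, float)
    depths = np.arange(len(sample_ages), dtype=float) if depths is None else depths
    return AgeModel(control_depths=np.arange(len(control_ages), dtype=float),
                    control_ages=np.asarray(control_ages, float),
                    sample_depths=depths, sample_ages=sample_ages,
                    flags=["interpolated"] * len(sample_ages))


def _counts(n, total=250):
    return PollenCounts(sample_ids=[f"s{i}" for i in range(n)],
                        depths=np.arange(n, dtype=float), taxa=["A"],
                        counts=np.full((n, 1), float(total)))


class TestScreenSamples:
    def test_near_date_retained(self):
        mask = screen_samples(_model([800.0], [0.0]), _counts(1, 250))
        assert mask.tolist() == [True]

    def test_wide_bracket_excluded(self):
        # 1500 yr from the nearest date, bracketing dates 7000 yr apart
        mask = screen_samples(_model([1500.0], [0.0, 7000.0]), _counts(1, 250))
        assert mask.tolist() == [False]

    def test_low_count_excluded(self):
        mask = screen_samples(_model([800.0], [0.0]), _counts(1, 199))
        assert mask.tolist() == [False]

    def test_bracketed_within_6kyr_retained(self):
        mask = screen_samples(_model([3000.0], [1200.0, 6800.0]), _counts(1, 300))
        assert mask.tolist() == [True]

    def test_idempotent_and_order_independent(self):
        model = _model([800.0, 1500.0, 3000.0], [0.0, 7000.0],
                       depths=np.array([0.0, 1.0, 2.0]))
        counts = _counts(3)
        m1 = screen_samples(model, counts)
        m2 = screen_samples(model, counts)
        np.testing.assert_array_equal(m1, m2)


def _record(n_controls=4, n_indep=2, span=9000.0, top=300.0, interval=200.0,
            region="W_EU"):
    n = max(int(span / interval) + 1, 5)
    ages = top + np.arange(n) * interval
    depths = np.arange(n, dtype=float)
    controls = []
    for i in range(n_controls):
        kind = "c14" if i < n_indep else "core_top"
        controls.append(AgeControl(depth=float(i), kind=kind,
                                   age=float(i) * 1000.0, sigma=50.0))
    counts = PollenCounts(sample_ids=[f"s{i}" for i in range(n)], depths=depths,
                          taxa=["A"], counts=np.full((n, 1), 300.0))
    rec = FossilRecord(site=Site(site_id="r", lat=50.0, lon=0.0, region_id=region),
                       counts=counts, controls=controls)
    rec.age_model = _model(ages, [c.age for c in controls], depths=depths)
    return rec


class TestScreenRecord:
    def test_good_record_passes(self):
        passed, reasons = screen_record(_record())
        assert passed and reasons == []

    def test_resolution_relaxed_in_northern_asia(self):
        # 600-yr median interval fails in western Europe but passes in northern Asia
        assert not screen_record(_record(interval=600.0, region="W_EU"))[0]
        assert screen_record(_record(interval=600.0, region="N_AS"))[0]

    def test_short_duration_fails(self):
        passed, reasons = screen_record(_record(span=4500.0))
        assert not passed
        assert any("duration" in r for r in reasons)

    def test_too_few_independent_dates(self):
        passed, reasons = screen_record(_record(n_indep=1))
        assert not passed
        assert any("independent" in r for r in reasons)

    def test_no_young_sample_fails(self):
        passed, reasons = screen_record(_record(top=1500.0))
        assert not passed
        assert any("younger" in r for r in reasons)


class TestAssignSiteClimate:
    @pytest.fixture(scope="class")
    def grid(self):
        return make_climate_field(n_lat=12, n_lon=12, corr_target=0.4, seed=5)

    def test_node_identity(self, grid):
        i, j = 4, 6
        site = Site(site_id="n", lat=float(grid.lat[i]), lon=float(grid.lon[j]),
                    elev=float(grid.elev[i, j]))
        triple = assign_site_climate(site, grid)
        months = grid.monthly_temp[:, i, j]
        assert triple.annt == pytest.approx(months.mean(), abs=1e-9)
        assert triple.mtwa == pytest.approx(months.max(), abs=1e-9)
        assert triple.mtco == pytest.approx(months.min(), abs=1e-9)

    def test_flat_field(self, grid):
        from pollenrecon.types import ClimateGrid
        flat = ClimateGrid(lat=grid.lat, lon=grid.lon,
                           monthly_temp=np.full_like(grid.monthly_temp, 7.5),
                           elev=np.zeros_like(grid.elev))
        site = Site(site_id="f", lat=40.3, lon=11.7, elev=0.0)
        triple = assign_site_climate(site, flat)
        assert triple.annt == pytest.approx(7.5)

    def test_lapse_adjustment(self, grid):
        i, j = 5, 5
        site = Site(site_id="h", lat=float(grid.lat[i]), lon=float(grid.lon[j]),
                    elev=float(grid.elev[i, j]) + 100.0)
        triple = assign_site_climate(site, grid, lapse_rate=-0.0065)
        base = grid.monthly_temp[:, i, j].mean()
        assert triple.annt == pytest.approx(base - 0.65, abs=1e-9)

    def test_outside_grid_errors(self, grid):
        with pytest.raises(ValidationError):
            assign_site_climate(Site(site_id="o", lat=-5.0, lon=0.0), grid)
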