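"""MAT, WA-PLS, cross-validation, h selection and significance testing."""

import numpy as np
import pandas as pd
import pytest

from pollenrecon.synthetic import (
    expected_proportions,
    make_calibration_set,
    make_climate_field,
    make_niches,
)
from pollenrecon.transfer import (
    MATRegressor,
    WAPLSRegressor,
    bootstrap_error,
    cross_validate,
    hblock_median_scd,
    mat_predict,
    scd,
    select_h,
    significance_test,
)
from pollenrecon.types import CalibrationSet, Site, ValidationError


class TestScd:
    def test_identity(self):
        assert scd([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_vectors_reach_two(self):
        assert scd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_hand_computed_value(self):
        expected = (np.sqrt(0.5) - np.sqrt(0.25)) ** 2 + (np.sqrt(0.5) - np.sqrt(0.75)) ** 2
        assert scd([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected, abs=1e-12)
        assert scd([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.0681, abs=1e-4)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            scd([-0.1, 1.1], [0.5, 0.5])

    def test_metric_properties_on_random_simplex_triples(self, rng):
        for _ in range(50):
            p, q, r = rng.dirichlet(np.ones(5), size=3)
            assert scd(p, q) == pytest.approx(scd(q, p), abs=1e-12)
            assert scd(p, p) == pytest.approx(0.0, abs=1e-12)
            # chord distance is a metric; squared version obeys the
            # triangle inequality through its square root
            assert np.sqrt(scd(p, r)) <= np.sqrt(scd(p, q)) + np.sqrt(scd(q, r)) + 1e-12


def _tiny_calib(features, climate_mtco):
    n = len(features)
    sites = [Site(site_id=f"c{i}", lat=20.0 + (i % 60) * 0.5,
                  lon=float((i * 3) % 360) - 180.0) for i in range(n)]
    climate = pd.DataFrame({"annt": np.asarray(climate_mtco, float) + 5.0,
                            "mtwa": np.asarray(climate_mtco, float) + 10.0,
                            "mtco": np.asarray(climate_mtco, float)})
    return CalibrationSet(sites=sites, feature_names=[f"f{j}" for j in
                          range(np.asarray(features).shape[1])],
                          features=np.asarray(features, float), climate=climate)


class TestMat:
    def test_k1_returns_nearest_climate(self):
        calib = _tiny_calib([[1, 0], [0, 1]], [-10.0, 0.0])
        est, diag = mat_predict([0.9, 0.1], calib, k=1, scd_max=np.inf)
        assert est[0, 2] == pytest.approx(-10.0)

    def test_equal_distances_average(self):
        calib = _tiny_calib([[1, 0], [0, 1]], [4.0, 8.0])
        est, _ = mat_predict([0.5, 0.5], calib, k=2, scd_max=np.inf)
        assert est[0, 2] == pytest.approx(6.0)

    def test_inverse_distance_weights_hand_oracle(self):
        """Three analogues at SCDs (.02,.04,.08), MTCO (-10,-6,-2) -> -7.714."""
        scds = np.array([0.02, 0.04, 0.08])
        mtco = np.array([-10.0, -6.0, -2.0])
        w = 1.0 / scds
        expected = float((w * mtco).sum() / w.sum())
        assert expected == pytest.approx(-7.714, abs=1e-3)
        # realize those exact SCDs with 2-d compositions against [0.5, 0.5]
        target = np.array([0.5, 0.5])
        feats = []
        for d in scds:
            # solve scd((a,1-a),(.5,.5)) = d on the simplex
            from scipy.optimize import brentq
            a = brentq(lambda a_: scd([a_, 1 - a_], target) - d, 0.5, 1.0 - 1e-9)
            feats.append([a, 1 - a])
        calib = _tiny_calib(feats, mtco)
        est, diag = mat_predict(target, calib, k=3, scd_max=np.inf)
        np.testing.assert_allclose(diag["analogue_scd"][0], scds, atol=1e-10)
        assert est[0, 2] == pytest.approx(expected, abs=1e-6)

    def test_convexity_of_estimates(self, rng):
        feats = rng.dirichlet(np.ones(4), size=20)
        mtco = rng.uniform(-20, 5, size=20)
        calib = _tiny_calib(feats, mtco)
        target = rng.dirichlet(np.ones(4))
        est, diag = mat_predict(target, calib, k=6, scd_max=np.inf)
        used = diag["analogue_idx"][0]
        assert mtco[used].min() - 1e-9 <= est[0, 2] <= mtco[used].max() + 1e-9

    def test_zero_distance_short_circuits(self):
        calib = _tiny_calib([[0.5, 0.5], [0.4, 0.6]], [-5.0, 20.0])
        est, _ = mat_predict([0.5, 0.5], calib, k=2, scd_max=np.inf)
        assert est[0, 2] == pytest.approx(-5.0)

    def test_no_analogue_flag_withholds_estimate(self):
        calib = _tiny_calib([[1, 0], [0.9, 0.1]], [0.0, 1.0])
        est, diag = mat_predict([0.0, 1.0], calib, k=1, scd_max=0.2)
        assert diag["no_analogue"][0]
        assert np.isnan(est[0, 2])

    def test_all_excluded_errors(self):
        calib = _tiny_calib([[1, 0], [0, 1]], [0.0, 1.0])
        with pytest.raises(ValidationError):
            mat_predict([0.5, 0.5], calib, exclude=lambda s: True)


class TestBootstrapError:
    def test_quadrature_combination(self, rng):
        """sample_error^2 = boot variance + rmsep^2 (3-4-5 style quadrature)."""
        feats = rng.dirichlet(np.ones(3), size=20)
        calib = _tiny_calib(feats, rng.uniform(-10, 10, 20))
        t = rng.dirichlet(np.ones(3), size=1)
        sd = bootstrap_error(t, calib, k=4, n_boot=60, rmsep=0.0, seed=5)
        combined = bootstrap_error(t, calib, k=4, n_boot=60, rmsep=0.4, seed=5)
        np.testing.assert_allclose(combined, np.sqrt(sd**2 + 0.4**2), atol=1e-12)

    def test_degenerate_limit_zero_error(self):
        feats = [[0.5, 0.5]] * 6
        calib = _tiny_calib(feats, [2.0] * 6)
        err = bootstrap_error([[0.5, 0.5]], calib, k=3, n_boot=30, rmsep=0.0, seed=1)
        assert err[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducible_and_monotone_in_rmsep(self, rng):
        feats = rng.dirichlet(np.ones(3), size=30)
        calib = _tiny_calib(feats, rng.uniform(-10, 10, 30))
        t = rng.dirichlet(np.ones(3), size=2)
        a = bootstrap_error(t, calib, k=5, n_boot=40, rmsep=0.5, seed=9)
        b = bootstrap_error(t, calib, k=5, n_boot=40, rmsep=0.5, seed=9)
        np.testing.assert_array_equal(a, b)
        c = bootstrap_error(t, calib, k=5, n_boot=40, rmsep=1.0, seed=9)
        assert np.all(c >= a)


class TestWapls:
    @pytest.fixture(scope="class")
    def gauss_data(self):
        """Gaussian-niche species responses along a known gradient."""
        rng = np.random.default_rng(11)
        n, m = 300, 20
        x = rng.uniform(0, 100, n)
        optima = np.linspace(0, 100, m)
        tol = 12.0
        mu = np.exp(-((x[:, None] - optima[None]) ** 2) / (2 * tol**2))
        Y = mu / mu.sum(axis=1, keepdims=True)
        return Y, x

    def test_one_component_equals_wa_with_inverse_deshrinking(self, gauss_data):
        """Independent two-step WA oracle: optima, site scores, OLS deshrink."""
        Y, x = gauss_data
        model = WAPLSRegressor(n_components=1).fit(Y, x)
        # oracle (equal row sums -> unweighted regression applies)
        u = (Y.T @ x) / Y.sum(axis=0)
        z = (Y @ u) / Y.sum(axis=1)
        A = np.column_stack([np.ones_like(z), z])
        beta = np.linalg.lstsq(A, x, rcond=None)[0]
        oracle = A @ beta
        np.testing.assert_allclose(model.fitted_values_, oracle, atol=1e-8)

    def test_training_r2_nondecreasing_in_components(self, gauss_data):
        Y, x = gauss_data
        model = WAPLSRegressor(n_components=4).fit(Y, x)
        r2 = [model.training_r2(a) for a in range(1, 5)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_recovers_gradient_on_noiseless_niche_data(self, gauss_data):
        Y, x = gauss_data
        model = WAPLSRegressor(n_components=2).fit(Y, x)
        pred = model.predict(Y)
        assert np.corrcoef(pred, x)[0, 1] > 0.95

    def test_excessive_components_rejected(self):
        Y = np.abs(np.random.default_rng(0).normal(size=(5, 3))) + 0.1
        with pytest.raises(ValidationError):
            WAPLSRegressor(n_components=5).fit(Y, np.arange(5.0))

    def test_classical_deshrinking_runs(self, gauss_data):
        Y, x = gauss_data
        model = WAPLSRegressor(n_components=1, deshrinking="classical").fit(Y, x)
        assert np.corrcoef(model.predict(Y), x)[0, 1] > 0.9


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def calib(self):
        field = make_climate_field(n_lat=20, n_lon=30, corr_target=0.5, seed=21)
        niches = make_niches(seed=22)
        return make_calibration_set(120, field, niches, seed=23)

    def test_h0_hblock_equals_loo(self, calib):
        loo = cross_validate(calib, scheme="loo")
        hb = cross_validate(calib, scheme="h_block", h=0.0)
        pd.testing.assert_frame_equal(loo.predictions, hb.predictions)

    def test_duplicated_sites_give_perfect_loo(self):
        feats = np.vstack([np.eye(3)] * 2) + 0.0
        mtco = np.tile([-10.0, -5.0, 0.0], 2)
        calib = _tiny_calib(feats, mtco)
        cv = cross_validate(calib, method="mat", scheme="loo", k=1)
        assert cv.r2["mtco"] == pytest.approx(1.0)
        assert cv.rmsep["mtco"] == pytest.approx(0.0, abs=1e-12)

    def test_hblock_no_easier_than_loo(self, calib):
        loo = cross_validate(calib, scheme="loo")
        hb = cross_validate(calib, scheme="h_block", h=500.0)
        assert hb.r2["mtco"] <= loo.r2["mtco"] + 0.02

    def test_wapls_cross_validation_runs(self, calib):
        cv = cross_validate(calib, method="wapls", n_comp=2)
        assert 0.0 <= cv.r2["mtco"] <= 1.0


class TestSelectH:
    @pytest.fixture(scope="class")
    def calib(self):
        field = make_climate_field(n_lat=16, n_lon=24, corr_target=0.5, seed=31)
        niches = make_niches(seed=32)
        return make_calibration_set(100, field, niches, seed=33, clustered=True)

    def test_median_curve_nondecreasing(self, calib):
        h_grid = np.array([0.0, 200.0, 500.0, 1000.0])
        meds = [hblock_median_scd(calib, h) for h in h_grid]
        assert np.all(np.diff(meds) >= -1e-12)

    def test_left_boundary(self, calib):
        h_star, _ = select_h(calib, np.array([1e9]))
        assert h_star == 1000.0            # fossil median above all -> max h
        h0 = hblock_median_scd(calib, 0.0)
        h_star, _ = select_h(calib, np.full(5, h0 * 0.5))
        assert h_star == 0.0

    def test_crossing_matches_hand_identification(self, calib):
        h_grid = np.arange(0.0, 1001.0, 250.0)
        meds = np.array([hblock_median_scd(calib, h) for h in h_grid])
        target = (meds[1] + meds[2]) / 2.0
        h_star, curve = select_h(calib, np.full(9, target), h_grid=h_grid)
        expected = h_grid[np.nonzero(meds >= target)[0][0]]
        assert h_star == expected

    def test_empty_fossil_list_errors(self, calib):
        with pytest.raises(ValidationError):
            select_h(calib, np.array([]))


def _sig_calib(n_features: int, n: int = 120, seed: int = 43) -> CalibrationSet:
    r = np.random.default_rng(seed)
    return _tiny_calib(r.dirichlet(np.ones(n_features), size=n),
                       r.uniform(-20.0, 5.0, size=n))


class TestSignificance:
    def test_own_pc1_is_maximal_constraint(self, rng):
        calib = _sig_calib(6)
        F = np.abs(rng.normal(size=(30, 6))) + 0.05
        Fc = F - F.mean(axis=0)
        Fc = Fc / Fc.std(axis=0, ddof=1)
        U, s, Vt = np.linalg.svd(Fc, full_matrices=False)
        pc1 = U[:, 0] * s[0]
        res = significance_test(F, pc1, calib, n_rand=49, seed=5)
        assert res.passed
        assert res.observed_var >= res.null_var.max()

    def test_constant_reconstruction_fails(self, rng):
        F = np.abs(rng.normal(size=(20, 5))) + 0.05
        res = significance_test(F, np.full(20, 3.0), _sig_calib(5), n_rand=19, seed=2)
        assert res.observed_var == 0.0
        assert not res.passed

    def test_quantile_one_requires_beating_every_null(self, rng):
        F = np.abs(rng.normal(size=(20, 5))) + 0.05
        recon = F[:, 0] * 2.0
        res = significance_test(F, recon, _sig_calib(5), n_rand=19, quantile=1.0, seed=3)
        assert res.passed == bool(res.observed_var > res.null_var.max())

    def test_matches_explicit_rda_variance(self, rng):
        """The closed-form explained fraction equals a full RDA fit."""
        from pollenrecon.ordination import rda
        F = np.abs(rng.normal(size=(25, 4))) + 0.05
        recon = rng.normal(size=25)
        res = significance_test(F, recon, _sig_calib(4), n_rand=1, seed=0)
        assert res.observed_var == pytest.approx(
            rda(F, recon, scale=True).var_explained, abs=1e-10)
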