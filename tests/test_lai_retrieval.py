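"""LUT inversion, the semi-empirical g(NDVI), windowed moments and the
Taylor scale-effect factor."""

import numpy as np
import pytest

from grassagb import (SpectralGrid, HyperspectralFeatures, build_lut, LUTTable,
                      invert_lai_lut, fit_semiempirical_g, SemiEmpiricalLAIFn,
                      QuadraticFn, NumericalBivariateFn, WindowMoments,
                      windowed_moments, compute_k, ScaledInversionConfig,
                      invert_lai_scaled)
from grassagb.lai_retrieval import exact_scale_bias


class TestInvertLAI:
    def test_exact_match_returns_entry_lai(self, small_lut):
        k = 137
        assert invert_lai_lut(small_lut.features[k], small_lut) == small_lut.lai[k]

    def test_equidistant_tie_takes_lower_index(self):
        lut = LUTTable([1.0, 3.0], {}, [[0.4], [0.6]], ("NDVI",))
        assert invert_lai_lut(np.array([0.5]), lut, q=1) == 1.0

    def test_q_average(self):
        lut = LUTTable([1.0, 3.0, 10.0], {}, [[0.4], [0.6], [5.0]], ("NDVI",))
        assert invert_lai_lut(np.array([0.5]), lut, q=2) == pytest.approx(2.0)

    def test_nonfinite_observation_rejected_with_count(self, small_lut, caplog):
        import logging
        obs = np.vstack([small_lut.features[0], np.full(small_lut.features.shape[1], np.nan)])
        with caplog.at_level(logging.WARNING, logger="grassagb"):
            out = invert_lai_lut(obs, small_lut)
        assert out[0] == small_lut.lai[0]
        assert np.isnan(out[1])
        assert any("non-finite" in r.message for r in caplog.records)

    def test_roundtrip_within_lut_spacing(self, grid61, small_lut):
        # noiseless forward simulation at fixed LAI values, inverted back
        spec = HyperspectralFeatures(grid61, small_lut.feature_names and
                                     tuple(float(n[3:]) for n in small_lut.feature_names
                                           if n.startswith("rho")))
        probe = build_lut(20, {"lai": (0.1, 5.9)}, spec, grid61, seed=99)
        est = invert_lai_lut(probe.features, small_lut)
        assert np.max(np.abs(est - probe.lai)) <= small_lut.lai_grid_spacing()

    def test_feature_mismatch_rejected(self, small_lut):
        with pytest.raises(ValueError, match="feature spec"):
            invert_lai_lut(np.zeros(3), small_lut)

    def test_empty_lut_unconstructible(self):
        with pytest.raises(ValueError, match="at least one"):
            LUTTable(np.array([]), {}, np.zeros((0, 1)), ("NDVI",))


class TestSemiEmpiricalG:
    def _cubic_lut(self, coeffs=(0.5, 2.0, -1.0, 4.0), n=200):
        rng = np.random.default_rng(0)
        ndvi = rng.uniform(0.05, 0.95, n)
        lai = np.polynomial.polynomial.polyval(ndvi, coeffs)
        feats = np.column_stack([ndvi, ndvi])
        return LUTTable(lai, {}, feats, ("NDVI", "OSAVI"))

    def test_model_in_class_recovery(self):
        coeffs = (0.5, 2.0, -1.0, 4.0)
        fn = fit_semiempirical_g(self._cubic_lut(coeffs))
        np.testing.assert_allclose(fn.coeffs, coeffs, atol=1e-8)
        assert fn.fit_rmse == pytest.approx(0.0, abs=1e-9)

    def test_analytic_partials_match_finite_differences(self):
        fn = fit_semiempirical_g(self._cubic_lut())
        n0, r0, h = 0.4, 0.1, 1e-5
        f = fn.f
        fn_n = (f(n0 + h, r0) - f(n0 - h, r0)) / (2 * h)
        fn_r = (f(n0, r0 + h) - f(n0, r0 - h)) / (2 * h)
        gn, gr = fn.grad(n0, r0)
        assert gn == pytest.approx(fn_n, rel=1e-5)
        assert gr == pytest.approx(fn_r, rel=1e-5)
        f_nn = (f(n0 + h, r0) - 2 * f(n0, r0) + f(n0 - h, r0)) / h ** 2
        f_rr = (f(n0, r0 + h) - 2 * f(n0, r0) + f(n0, r0 - h)) / h ** 2
        f_nr = (f(n0 + h, r0 + h) - f(n0 + h, r0 - h)
                - f(n0 - h, r0 + h) + f(n0 - h, r0 - h)) / (4 * h ** 2)
        h_nn, h_rr, h_nr = fn.hessian(n0, r0)
        assert h_nn == pytest.approx(f_nn, rel=1e-4)
        assert h_rr == pytest.approx(f_rr, rel=1e-4)
        assert h_nr == pytest.approx(f_nr, rel=1e-4)

    def test_linear_g_reduces_to_pure_gradient_chain_rule(self):
        # g(v) = a + b v has g'' = 0: the Hessian of f = g(NDVI) collapses to
        # b * Hessian(NDVI), derived symbolically:
        #   v_NN = -4R/s^3, v_RR = 4N/s^3, v_NR = 2(N-R)/s^3,  s = N + R
        a, b = 0.7, 2.3
        fn = SemiEmpiricalLAIFn(np.array([a, b]))
        n0, r0 = 0.45, 0.12
        s = n0 + r0
        h_nn, h_rr, h_nr = fn.hessian(n0, r0)
        assert h_nn == pytest.approx(b * (-4 * r0 / s ** 3), rel=1e-12)
        assert h_rr == pytest.approx(b * (4 * n0 / s ** 3), rel=1e-12)
        assert h_nr == pytest.approx(b * (2 * (n0 - r0) / s ** 3), rel=1e-12)

    def test_rank_deficient_design_rejected(self):
        lut = LUTTable(np.linspace(1, 2, 20), {},
                       np.column_stack([np.full(20, 0.5), np.full(20, 0.5)]),
                       ("NDVI", "OSAVI"))
        with pytest.raises(ValueError, match="distinct NDVI"):
            fit_semiempirical_g(lut)


class TestWindowedMoments:
    def test_constant_rasters(self):
        m = windowed_moments(np.full((8, 8), 0.4), np.full((8, 8), 0.1), factor=4)
        np.testing.assert_allclose(m.nir_mean, 0.4)
        np.testing.assert_allclose(m.var_nir, 0.0)
        np.testing.assert_allclose(m.cov, 0.0)

    def test_checkerboard_closed_form(self):
        nir = np.array([[0.0, 1.0], [0.0, 1.0]])
        red = np.array([[0.0, 0.0], [1.0, 1.0]])
        m = windowed_moments(nir, red, factor=2)
        assert m.var_nir[0, 0] == pytest.approx(0.25)
        assert m.var_r[0, 0] == pytest.approx(0.25)
        assert m.cov[0, 0] == pytest.approx(0.0)
        assert m.n[0, 0] == 4

    def test_matches_bruteforce_two_pass(self):
        rng = np.random.default_rng(9)
        nir, red = rng.random((40, 40)), rng.random((40, 40))
        m = windowed_moments(nir, red, factor=40)
        # brute-force population moments
        nm, rm = nir.mean(), red.mean()
        assert m.nir_mean[0, 0] == pytest.approx(nm, abs=1e-12)
        assert m.var_nir[0, 0] == pytest.approx(np.mean((nir - nm) ** 2), abs=1e-12)
        assert m.var_r[0, 0] == pytest.approx(np.mean((red - rm) ** 2), abs=1e-12)
        assert m.cov[0, 0] == pytest.approx(np.mean((nir - nm) * (red - rm)), abs=1e-12)

    def test_cauchy_schwarz_invariant(self):
        rng = np.random.default_rng(10)
        m = windowed_moments(rng.random((20, 20)), rng.random((20, 20)), factor=5)
        assert np.all(np.abs(m.cov) <= np.sqrt(m.var_nir * m.var_r) + 1e-12)

    def test_fallback_window_tagged(self):
        rng = np.random.default_rng(11)
        m = windowed_moments(rng.random((50, 50)), rng.random((50, 50)), window=40)
        assert m.method == "fallback-window"
        assert np.all(m.var_nir >= 0)

    def test_zero_valid_footprint_flagged(self, caplog):
        import logging
        nir = np.ones((4, 4))
        valid = np.ones((4, 4), bool)
        valid[:2, :2] = False
        with caplog.at_level(logging.WARNING, logger="grassagb"):
            m = windowed_moments(nir, nir, factor=2, valid=valid)
        assert np.isnan(m.nir_mean[0, 0])
        assert m.n[0, 0] == 0


class TestComputeK:
    def test_homogeneous_footprint_gives_zero(self):
        fn = QuadraticFn(a=3.0, c=1.0)
        z = np.zeros((3, 3))
        m = WindowMoments(np.full((3, 3), 0.4), np.full((3, 3), 0.1), z, z, z,
                          np.full((3, 3), 16))
        np.testing.assert_array_equal(compute_k(m, fn).k, 0.0)

    def test_quadratic_hand_value(self):
        # f = NIR^2: k = -1/2 * 2 * VAR_NIR = -0.01
        m = WindowMoments(np.array([[0.4]]), np.array([[0.1]]), np.array([[0.01]]),
                          np.array([[0.0]]), np.array([[0.0]]), np.array([[4]]))
        assert compute_k(m, QuadraticFn(a=1.0)).k[0, 0] == pytest.approx(-0.01)

    def test_quadratic_exactness_against_bruteforce(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            fn = QuadraticFn(*rng.uniform(-2, 2, 6))
            nir = rng.uniform(0.2, 0.6, (8, 8))
            red = rng.uniform(0.05, 0.3, (8, 8))
            k = compute_k(windowed_moments(nir, red, factor=8), fn).k[0, 0]
            exact = exact_scale_bias(nir, red, 8, fn)[0, 0]
            assert k == pytest.approx(exact, abs=1e-10)

    def test_undefined_means_flagged(self, caplog):
        import logging
        z = np.zeros((1, 1))
        m = WindowMoments(np.array([[0.0]]), np.array([[0.0]]), z.copy(), z.copy(),
                          z.copy(), np.array([[4]]))
        with caplog.at_level(logging.WARNING, logger="grassagb"):
            out = compute_k(m, QuadraticFn(a=1.0))
        assert np.isnan(out.k[0, 0])

    def test_numerical_hessian_wrapper_close_to_analytic(self):
        fn = SemiEmpiricalLAIFn(np.array([0.2, 1.5, -0.8, 2.0]))
        num = NumericalBivariateFn(fn.f)
        a = fn.hessian(0.45, 0.12)
        b = num.hessian(0.45, 0.12)
        np.testing.assert_allclose(a, b, rtol=1e-4)


class TestScaledInversion:
    def _lut(self):
        lai = np.linspace(0.0, 5.0, 51)
        bands = np.column_stack([0.1 + 0.05 * lai, 0.3 - 0.04 * lai])
        feats = np.column_stack([bands, (bands[:, 0] - bands[:, 1])
                                 / (bands[:, 0] + bands[:, 1])])
        return LUTTable(lai, {}, feats, ("nir", "red", "NDVI"))

    def test_reduces_to_plain_inversion_without_prior(self):
        lut = self._lut()
        rng = np.random.default_rng(13)
        obs = np.column_stack([rng.uniform(0.1, 0.35, 30), rng.uniform(0.1, 0.3, 30)])
        cfg = ScaledInversionConfig(eps_lai=np.inf)
        scaled = invert_lai_scaled(obs, lut, k=0.0, config=cfg,
                                   band_feature_indices=[0, 1])
        # plain inversion on the band features only: equal per-band errors
        cfg_eq = ScaledInversionConfig(band_error=np.array([1.0, 1.0]), eps_lai=np.inf)
        plain = invert_lai_scaled(obs, lut, k=0.0, config=cfg_eq,
                                  band_feature_indices=[0, 1])
        band_lut = LUTTable(lut.lai, {}, lut.features[:, :2], ("nir", "red"))
        expect = invert_lai_lut(obs, band_lut)
        np.testing.assert_array_equal(plain, expect)
        assert scaled.shape == expect.shape

    def test_prior_dominated_limit_returns_entry_nearest_expectation_plus_k(self):
        lut = self._lut()
        cfg = ScaledInversionConfig(band_error=np.array([1e12, 1e12]),
                                    eps_lai=1e-12, lai_expectation=1.5)
        out = invert_lai_scaled(np.array([[0.2, 0.2]]), lut, k=0.3, config=cfg,
                                band_feature_indices=[0, 1])
        assert out[0] == pytest.approx(1.8, abs=0.051)  # nearest grid value to 1.8

    def test_never_outside_lut_range(self):
        lut = self._lut()
        rng = np.random.default_rng(14)
        obs = rng.uniform(0.0, 0.5, (100, 2))
        out = invert_lai_scaled(obs, lut, k=rng.normal(0, 0.5, 100),
                                config=ScaledInversionConfig(),
                                band_feature_indices=[0, 1])
        assert np.nanmin(out) >= lut.lai.min() and np.nanmax(out) <= lut.lai.max()

    def test_missing_k_falls_back_to_zero(self, caplog):
        import logging
        lut = self._lut()
        obs = np.array([[0.2, 0.25], [0.2, 0.25]])
        with caplog.at_level(logging.WARNING, logger="grassagb"):
            a = invert_lai_scaled(obs, lut, k=np.array([np.nan, 0.0]),
                                  config=ScaledInversionConfig(),
                                  band_feature_indices=[0, 1])
        assert a[0] == a[1]
        assert any("missing k" in r.message for r in caplog.records)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScaledInversionConfig(eps_lai=0.0)
        with pytest.raises(ValueError):
            ScaledInversionConfig(q=0)
        with pytest.raises(ValueError):
            ScaledInversionConfig(band_error=np.array([0.0, 1.0]))
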