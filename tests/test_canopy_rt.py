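"""Forward canopy model, SRF convolution and LUT construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grassagb import (SpectralGrid, CanopyState, BeerLambertCanopy, SensorSRF,
                      simulate_reflectance, convolve_srf, gf2_srf, build_lut,
                      HyperspectralFeatures, default_leaf_spectrum,
                      default_soil_spectrum, GF2_BAND_RANGES_NM)


@pytest.fixture
def grid5():
    return SpectralGrid(np.array([450.0, 550.0, 650.0, 750.0, 850.0]))


class TestBeerLambert:
    def test_zero_lai_returns_soil_exactly(self, grid5):
        leaf = np.full(5, 0.4)
        soil = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        out = simulate_reflectance(CanopyState(0.0, leaf, soil), grid5)
        np.testing.assert_array_equal(out, soil)

    def test_dense_canopy_converges_to_leaf(self, grid5):
        leaf = np.full(5, 0.45)
        soil = np.full(5, 0.2)
        out = simulate_reflectance(CanopyState(50.0, leaf, soil, g=0.5), grid5)
        np.testing.assert_allclose(out, leaf, atol=1e-5)

    def test_closed_form_hand_value(self, grid5):
        # P = exp(-0.5*2/cos 0) = e^-1; rho = (1-P)*0.5 + P*0.2
        out = simulate_reflectance(
            CanopyState(2.0, np.full(5, 0.5), np.full(5, 0.2), g=0.5,
                        sun_zenith_deg=0.0), grid5)
        p = np.exp(-1.0)
        np.testing.assert_allclose(out, (1 - p) * 0.5 + p * 0.2, rtol=1e-12)
        assert out[0] == pytest.approx(0.3896, abs=5e-5)

    def test_monotone_in_lai_and_bounded(self, grid5):
        leaf = default_leaf_spectrum(grid5)
        soil = default_soil_spectrum(grid5)
        lais = np.linspace(0, 8, 30)
        spectra = np.array([simulate_reflectance(CanopyState(l, leaf, soil), grid5)
                            for l in lais])
        assert spectra.min() >= 0 and spectra.max() <= 1
        for b in range(5):
            diffs = np.diff(spectra[:, b])
            if leaf[b] > soil[b]:
                assert np.all(diffs >= 0)
            elif leaf[b] < soil[b]:
                assert np.all(diffs <= 0)

    def test_mismatched_grid_rejected(self, grid5):
        with pytest.raises(ValueError, match="grid"):
            simulate_reflectance(CanopyState(1.0, np.full(4, 0.3), np.full(4, 0.2)),
                                 grid5)

    def test_state_invariants(self, grid5):
        with pytest.raises(ValueError):
            CanopyState(-1.0, np.full(5, 0.3), np.full(5, 0.2))
        with pytest.raises(ValueError):
            CanopyState(1.0, np.full(5, 1.3), np.full(5, 0.2))
        with pytest.raises(ValueError):
            CanopyState(1.0, np.full(5, 0.3), np.full(5, 0.2), sun_zenith_deg=90.0)


class TestSRF:
    def test_constant_spectrum_maps_to_itself(self, grid5):
        srf = SensorSRF.boxcar(grid5, {"a": (400, 600), "b": (600, 900)})
        np.testing.assert_allclose(convolve_srf(np.full(5, 0.3), srf), 0.3)

    def test_boxcar_on_linear_spectrum_gives_midpoint(self):
        grid = SpectralGrid(np.linspace(400.0, 1000.0, 601))  # 1 nm steps
        spectrum = 0.001 * (grid.wavelengths_nm - 400.0) / 600.0 * 600 + 0.1
        srf = SensorSRF.boxcar(grid, GF2_BAND_RANGES_NM)
        out = convolve_srf(spectrum, srf)
        for k, (lo, hi) in enumerate(GF2_BAND_RANGES_NM.values()):
            mid = 0.001 * ((lo + hi) / 2 - 400.0) + 0.1
            assert out[k] == pytest.approx(mid, rel=1e-12)

    def test_matches_bruteforce_weighted_sum(self, grid5):
        rng = np.random.default_rng(5)
        w = rng.random((3, 5))
        srf = SensorSRF(grid5, ("x", "y", "z"), w)
        spectrum = rng.random(5)
        expected = [float(np.sum(srf.weights[b] * spectrum)) for b in range(3)]
        np.testing.assert_allclose(convolve_srf(spectrum, srf), expected, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(-0.5, 0.5), b=st.floats(-0.5, 0.5))
    def test_linearity(self, a, b):
        grid = SpectralGrid(np.linspace(400, 1000, 13))
        rng = np.random.default_rng(3)
        s1, s2 = rng.random(13), rng.random(13)
        srf = SensorSRF.boxcar(grid, {"v": (450, 700), "n": (700, 950)})
        lhs = convolve_srf(a * s1 + b * s2, srf)
        rhs = a * convolve_srf(s1, srf) + b * convolve_srf(s2, srf)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_empty_band_support_rejected(self, grid5):
        with pytest.raises(ValueError, match="outside the spectral grid"):
            SensorSRF.boxcar(grid5, {"uv": (350, 360)})

    def test_cube_convolution_matches_per_pixel(self):
        rng = np.random.default_rng(8)
        cube = rng.random((61, 3, 4))
        srf = gf2_srf(SpectralGrid(np.linspace(400, 1000, 61)))
        out = convolve_srf(cube, srf)
        for r in range(3):
            for c in range(4):
                np.testing.assert_allclose(out[:, r, c],
                                           convolve_srf(cube[:, r, c], srf), atol=1e-12)

    def test_from_csv_interpolates(self, tmp_path, grid5):
        rows = ["band,wavelength_nm,weight"]
        rows += [f"g,{w},1.0" for w in (500, 600)]
        (tmp_path / "srf.csv").write_text("\n".join(rows) + "\n")
        srf = SensorSRF.from_csv(tmp_path / "srf.csv", grid5)
        assert srf.band_names == ("g",)
        assert srf.weights[0, 1] > 0 and srf.weights[0, 4] == 0


class TestBuildLUT:
    def test_single_entry_point_ranges_equals_direct_simulation(self, grid5):
        spec = HyperspectralFeatures(grid5, (550.0, 750.0), red_nm=650.0, nir_nm=850.0)
        lut = build_lut(1, {"lai": (2.0, 2.0)}, spec, grid5, seed=0)
        leaf, soil = default_leaf_spectrum(grid5), default_soil_spectrum(grid5)
        direct = simulate_reflectance(CanopyState(2.0, leaf, soil), grid5)
        np.testing.assert_allclose(lut.features[0],
                                   spec.from_spectra(direct[None, :])[0], atol=1e-12)
        assert lut.lai[0] == 2.0

    def test_seeded_determinism(self, grid5):
        spec = HyperspectralFeatures(grid5, (550.0,), red_nm=650.0, nir_nm=850.0)
        ranges = {"lai": (0.0, 6.0), "soil_scale": (0.8, 1.2)}
        a = build_lut(200, ranges, spec, grid5, seed=42)
        b = build_lut(200, ranges, spec, grid5, seed=42)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.lai, b.lai)
        assert hash(a.features.tobytes()) == hash(b.features.tobytes())

    def test_lut_ndvi_monotone_in_lai_sweep(self, grid5):
        # 1-D LAI sweep with all other parameters fixed
        spec = HyperspectralFeatures(grid5, (550.0,), red_nm=650.0, nir_nm=850.0)
        lut = build_lut(300, {"lai": (0.0, 6.0)}, spec, grid5, seed=7)
        order = np.argsort(lut.lai)
        ndvi = lut.feature_column("NDVI")[order]
        assert np.all(np.diff(ndvi) >= -1e-12)

    def test_unknown_parameter_rejected(self, grid5):
        spec = HyperspectralFeatures(grid5, (550.0,), red_nm=650.0, nir_nm=850.0)
        with pytest.raises(ValueError, match="unsupported"):
            build_lut(5, {"lai": (0, 1), "chlorophyll": (20, 60)}, spec, grid5, seed=0)

    def test_feature_outside_grid_rejected(self, grid5):
        spec = HyperspectralFeatures(grid5, (550.0,), red_nm=650.0, nir_nm=850.0)
        bad = SpectralGrid(np.array([400.0, 500.0]))
        lut_spec = HyperspectralFeatures(bad, (450.0,))
        with pytest.raises(ValueError, match="grid"):
            lut_spec.from_spectra(np.random.default_rng(0).random((3, 5)))

    def test_lai_grid_spacing(self, grid5):
        spec = HyperspectralFeatures(grid5, (550.0,), red_nm=650.0, nir_nm=850.0)
        lut = build_lut(1000, {"lai": (0.0, 6.0)}, spec, grid5, seed=1)
        srt = np.sort(lut.lai)
        assert lut.lai_grid_spacing() == pytest.approx(np.max(np.diff(srt)))
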