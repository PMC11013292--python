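"""Synthetic scene generator: field statistics, allometry, rendering and
plot sampling."""

import numpy as np
import pytest
from dataclasses import replace

from grassagb import (SceneConfig, generate_lai_field, lai_to_agb, render_scene,
                      write_scene, read_cube, read_plots, AggregationSpec,
                      aggregate_map, convolve_srf)
from grassagb.synthetic_scene import treatment_blocks


def _flat_config(**kw):
    defaults = dict(shape=(48, 48), factor=8, n_plots=12, block_grid=(2, 3),
                    correlation_length_px=4.0, spectral_bands=31, seed=3)
    defaults.update(kw)
    return SceneConfig(**defaults)


class TestLAIField:
    def test_seeded_determinism_is_bit_identical(self, tiny_config):
        a = generate_lai_field(tiny_config)
        b = generate_lai_field(tiny_config)
        np.testing.assert_array_equal(a, b)

    def test_zero_heterogeneity_constant_within_blocks(self):
        cfg = _flat_config(heterogeneity=0.0)
        field = generate_lai_field(cfg)
        _, labels, slices = treatment_blocks(cfg)
        mid = 0.5 * (cfg.lai_range[0] + cfg.lai_range[1])
        for label, sl in zip(labels, slices):
            block = field[sl]
            assert np.ptp(block) == 0.0
            assert block[0, 0] == pytest.approx(mid * cfg.treatments[label])

    def test_variance_increases_monotonically_with_amplitude(self):
        # Monte-Carlo over 20 seeds: rank correlation between amplitude and
        # achieved variance must exceed 0.9
        from scipy.stats import spearmanr
        amps = [0.1, 0.3, 0.5, 0.7, 0.9]
        mean_var = []
        for amp in amps:
            v = []
            for seed in range(20):
                cfg = _flat_config(heterogeneity=amp, seed=seed,
                                   treatments={k: 1.0 for k in
                                               ("CK", "M", "O4", "O7", "I4", "I7")})
                v.append(generate_lai_field(cfg).var())
            mean_var.append(np.mean(v))
        rho, _ = spearmanr(amps, mean_var)
        assert rho > 0.9
        assert np.all(np.diff(mean_var) > 0)

    def test_field_within_physical_bounds(self, tiny_config):
        field = generate_lai_field(tiny_config)
        assert field.min() >= 0.0
        max_mult = max(tiny_config.treatments.values())
        assert field.max() <= tiny_config.lai_range[1] * max_mult + 1e-9

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divide"):
            _flat_config(factor=7)
        with pytest.raises(ValueError, match="LAI range"):
            _flat_config(lai_range=(-1.0, 4.0))
        with pytest.raises(ValueError, match="positive"):
            _flat_config(correlation_length_px=0.0)
        with pytest.raises(ValueError, match="allometry"):
            _flat_config(alpha=-5.0)


class TestAllometry:
    def test_power_law_through_origin(self):
        cfg = _flat_config(agb_noise_cv=0.0)
        assert lai_to_agb(np.array(0.0), cfg) == 0.0

    def test_linear_noiseless_hand_value(self):
        cfg = _flat_config(alpha=200.0, beta=1.0, agb_noise_cv=0.0)
        assert lai_to_agb(np.array(2.0), cfg) == pytest.approx(400.0)

    def test_loglog_regression_recovers_allometry(self):
        cfg = _flat_config(alpha=180.0, beta=1.35, agb_noise_cv=0.0,
                           heterogeneity=0.8)
        lai = generate_lai_field(cfg)
        agb = lai_to_agb(lai, cfg)
        mask = lai > 0
        slope, intercept = np.polyfit(np.log(lai[mask]), np.log(agb[mask]), 1)
        assert slope == pytest.approx(1.35, abs=1e-6)
        assert np.exp(intercept) == pytest.approx(180.0, rel=1e-6)

    def test_noise_is_mean_one(self):
        cfg = _flat_config(shape=(96, 96), factor=8, agb_noise_cv=0.3, seed=1)
        lai = np.full(cfg.shape, 2.0)
        agb = lai_to_agb(lai, cfg, np.random.default_rng(5))
        clean = cfg.alpha * 2.0 ** cfg.beta
        assert agb.mean() == pytest.approx(clean, rel=0.1)
        assert agb.min() >= 0

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            lai_to_agb(np.array([-0.1]), _flat_config())


class TestRenderScene:
    def test_zero_noise_constant_lai_gives_constant_images(self):
        cfg = _flat_config(heterogeneity=0.0, reflectance_noise_sd=0.0,
                           agb_noise_cv=0.0, soil_scale_range=(1.0, 1.0),
                           treatments={k: 1.0 for k in
                                       ("CK", "M", "O4", "O7", "I4", "I7")})
        scene = render_scene(cfg)
        for band in scene.uav_cube.data:
            assert np.ptp(band) == pytest.approx(0.0, abs=1e-7)
        for band in scene.satellite.data:
            assert np.ptp(band) == pytest.approx(0.0, abs=1e-7)

    def test_aggregation_identity_without_noise(self):
        cfg = _flat_config(reflectance_noise_sd=0.0)
        scene = render_scene(cfg)
        fine_bands = convolve_srf(scene.uav_cube.data.astype(float), scene.srf)
        f = cfg.factor
        for b in range(fine_bands.shape[0]):
            block_mean = aggregate_map(fine_bands[b], AggregationSpec(f))
            np.testing.assert_allclose(scene.satellite.data[b], block_mean, atol=1e-6)

    def test_reflectance_everywhere_in_unit_interval(self, tiny_scene):
        assert tiny_scene.uav_cube.data.min() >= 0.0
        assert tiny_scene.uav_cube.data.max() <= 1.0
        assert tiny_scene.satellite.data.min() >= 0.0
        assert tiny_scene.satellite.data.max() <= 1.0

    def test_agb_conservation_under_aggregation(self):
        # zero noise: block mean of fine AGB is the coarse truth
        cfg = _flat_config(agb_noise_cv=0.0, reflectance_noise_sd=0.0)
        scene = render_scene(cfg)
        coarse = aggregate_map(scene.agb.data, AggregationSpec(cfg.factor))
        assert coarse.mean() == pytest.approx(scene.agb.data.mean(), rel=1e-10)

    def test_plots_match_fine_rasters_before_measurement_noise(self):
        cfg = _flat_config(plot_noise_sd_frac=0.0)
        scene = render_scene(cfg)
        meta = scene.lai.meta
        half = int(round(cfg.plot_esu_m / cfg.fine_pixel_m / 2))
        for p in scene.plots:
            c, r = meta.xy_to_colrow(p.x, p.y)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            block = scene.agb.data[r0 - half + 1:r0 + half + 1,
                                   c0 - half + 1:c0 + half + 1]
            assert p.agb_g_m2 == pytest.approx(block.mean(), rel=1e-9)

    def test_plot_minimum_separation_one_coarse_pixel(self, tiny_scene):
        cfg = tiny_scene.config
        xy = np.array([[p.x, p.y] for p in tiny_scene.plots])
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.factor * cfg.fine_pixel_m - 1e-9

    def test_scene_determinism(self, tiny_config):
        a = render_scene(tiny_config)
        b = render_scene(tiny_config)
        np.testing.assert_array_equal(a.uav_cube.data, b.uav_cube.data)
        np.testing.assert_array_equal(a.satellite.data, b.satellite.data)
        assert a.plots == b.plots

    def test_coarse_footprint_is_factor_times_fine(self, tiny_scene):
        fine, sat = tiny_scene.lai.meta, tiny_scene.satellite.meta
        assert sat.pixel_x == pytest.approx(fine.pixel_x * tiny_scene.config.factor)

    def test_write_scene_roundtrip(self, tiny_scene, tmp_path):
        paths = write_scene(tiny_scene, tmp_path / "scene")
        cube = read_cube(paths["uav_cube"])
        np.testing.assert_allclose(cube.data, tiny_scene.uav_cube.data, atol=1e-7)
        plots = read_plots(paths["plots"])
        assert len(plots) == len(tiny_scene.plots)
        assert cube.provenance["seed"] == tiny_scene.config.seed
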