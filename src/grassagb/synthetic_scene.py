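"""Synthetic heterogeneous grassland scenes.

Generates the full multi-scale observation stack the mapping method
consumes, with the statistical structure the method assumes: a spatially
correlated fine-resolution LAI field organized into fertilization/mowing
treatment blocks, an allometric AGB field (AGB = alpha * LAI^beta with
multiplicative lognormal noise), a UAV-scale hyperspectral reflectance
cube rendered through the pluggable forward canopy model, a satellite
multispectral image produced by sensor-SRF convolution followed by block
aggregation, and a table of square ground plots sampled from the fine
fields with additive measurement noise.

Defaults emulate a degraded-steppe fertilization trial: 0.1 m UAV pixels aggregated
by a factor of 40 to 4 m satellite pixels, 90 plots of 1 m x 1 m split
evenly over six treatment blocks (control CK, mowing M, organic/inorganic
fertilization in April/July: O4, O7, I4, I7), whose LAI multipliers are
calibrated so block AGB means approximate a reference set of treatment means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geo_io import (Raster, RasterMeta, PlotSample, make_provenance,
                     write_raster, write_cube, write_plots)
from .canopy_rt import (SpectralGrid, BeerLambertCanopy, SensorSRF, gf2_srf,
                        default_leaf_spectrum, default_soil_spectrum, convolve_srf)

__all__ = ["SceneConfig", "SyntheticScene", "generate_lai_field", "lai_to_agb",
           "render_scene", "write_scene", "DEFAULT_TREATMENTS"]

log = logging.getLogger("grassagb")

#: Default per-treatment LAI multipliers.  Fertilized/mown AGB-to-control
#: ratios follow the reference treatment means (CK 423.23, I4 605.30,
#: O4 622.54, I7 562.75, O7 584.52 g/m2; mowing assumed 0.8); since
#: AGB ~ LAI^beta, the LAI multiplier is ratio^(1/beta) with beta = 1.2.
DEFAULT_TREATMENTS = {
    "CK": 1.0,
    "M": 0.8 ** (1 / 1.2),
    "O4": (622.54 / 423.23) ** (1 / 1.2),
    "O7": (584.52 / 423.23) ** (1 / 1.2),
    "I4": (605.30 / 423.23) ** (1 / 1.2),
    "I7": (562.75 / 423.23) ** (1 / 1.2),
}


@dataclass
class SceneConfig:
    """Study-scene parameters (defaults are the package's standard
    synthetic conditions; see docs/methods.md for rationale)."""

    shape: tuple = (400, 600)            # fine (rows, cols)
    fine_pixel_m: float = 0.1
    factor: int = 40                     # fine pixels per coarse pixel per axis
    lai_range: tuple = (0.2, 4.0)        # m2/m2
    correlation_length_px: float = 10.0  # fine pixels (1 m vegetation patches)
    heterogeneity: float = 1.0           # scales LAI deviations around the range midpoint
    alpha: float = 150.0                 # AGB = alpha * LAI^beta, g/m2
    beta: float = 1.2
    agb_noise_cv: float = 0.25           # multiplicative lognormal CV
    reflectance_noise_sd: float = 0.005  # additive, absolute reflectance
    soil_scale_range: tuple = (0.6, 1.4)  # spatial soil-brightness multiplier range
    soil_correlation_factor: float = 1.0  # soil patch scale relative to LAI patches
    n_plots: int = 90
    plot_esu_m: float = 1.0
    plot_noise_sd_frac: float = 0.05     # additive Gaussian on plot AGB/LAI, fraction of value
    treatments: dict = field(default_factory=lambda: dict(DEFAULT_TREATMENTS))
    block_grid: tuple = (2, 3)           # treatment blocks (rows, cols)
    spectral_bands: int = 61             # rendering grid over 400-1000 nm
    g: float = 0.5
    sun_zenith_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        nr, nc = self.shape
        if nr <= 0 or nc <= 0:
            raise ValueError("grid shape must be positive")
        if self.factor < 1 or nr % self.factor or nc % self.factor:
            raise ValueError("aggregation factor must be >= 1 and divide the grid shape")
        if self.lai_range[0] < 0 or self.lai_range[1] < self.lai_range[0]:
            raise ValueError("LAI range must satisfy 0 <= min <= max")
        if self.correlation_length_px <= 0:
            raise ValueError("correlation length must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("allometry coefficients must be positive")
        for name in ("heterogeneity", "agb_noise_cv", "reflectance_noise_sd",
                     "plot_noise_sd_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.soil_scale_range[0] <= self.soil_scale_range[1]):
            raise ValueError("soil scale range must satisfy 0 < lo <= hi")
        br, bc = self.block_grid
        if len(self.treatments) != br * bc:
            raise ValueError("treatments must provide one label per block")
        if nr % br or nc % bc:
            raise ValueError("block grid must divide the scene shape")

    @property
    def coarse_shape(self) -> tuple:
        return (self.shape[0] // self.factor, self.shape[1] // self.factor)

    def fine_meta(self, units="m2/m2", **kw) -> RasterMeta:
        return RasterMeta(origin_x=0.0, origin_y=(self.shape[0] - 1) * self.fine_pixel_m,
                          pixel_x=self.fine_pixel_m, pixel_y=self.fine_pixel_m,
                          units=units, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def _child_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def treatment_blocks(config: SceneConfig):
    """(label raster of block indices, ordered labels, block slices)."""
    nr, nc = config.shape
    br, bc = config.block_grid
    hr, hc = nr // br, nc // bc
    labels = list(config.treatments)
    raster = np.zeros((nr, nc), dtype=np.int16)
    slices = []
    for b in range(br):
        for c in range(bc):
            idx = b * bc + c
            sl = (slice(b * hr, (b + 1) * hr), slice(c * hc, (c + 1) * hc))
            raster[sl] = idx
            slices.append(sl)
    return raster, labels, slices


def generate_lai_field(config: SceneConfig, rng=None) -> np.ndarray:
    """Correlated random LAI field.

    Gaussian white noise smoothed at the configured correlation length is
    min-max rescaled to span the LAI range; the heterogeneity amplitude
    then scales deviations around the range midpoint (0 = constant field),
    and per-treatment LAI multipliers are applied inside their blocks."""
    rng = rng or np.random.default_rng(config.seed)
    nr, nc = config.shape
    lo, hi = config.lai_range
    mid = 0.5 * (lo + hi)
    if config.heterogeneity == 0:
        field_ = np.full((nr, nc), mid)
    else:
        z = ndimage.gaussian_filter(rng.standard_normal((nr, nc)),
                                    sigma=config.correlation_length_px / 2.0,
                                    mode="wrap")
        zmin, zmax = z.min(), z.max()
        u = (z - zmin) / (zmax - zmin) if zmax > zmin else np.full_like(z, 0.5)
        field_ = mid + config.heterogeneity * (u - 0.5) * (hi - lo)
        field_ = np.clip(field_, lo, hi)
    raster, labels, slices = treatment_blocks(config)
    for label, sl in zip(labels, slices):
        field_[sl] = field_[sl] * config.treatments[label]
    return np.maximum(field_, 0.0)


def lai_to_agb(lai: np.ndarray, config: SceneConfig, rng=None) -> np.ndarray:
    """Allometric AGB = alpha * LAI^beta with multiplicative lognormal
    noise of the configured CV (mean-one).

    For 2-D fields the noise is spatially correlated at the vegetation
    patch scale (the configured correlation length): allometric scatter
    reflects patch-to-patch differences in species composition and canopy
    structure, so it must not average away inside a 1 m2 plot or a coarse
    pixel footprint the way independent per-pixel noise would."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be >= 0")
    agb = config.alpha * lai ** config.beta
    if config.agb_noise_cv > 0:
        rng = rng or np.random.default_rng(config.seed)
        sigma = np.sqrt(np.log1p(config.agb_noise_cv ** 2))
        z = rng.standard_normal(agb.shape)
        if agb.ndim == 2:
            z = ndimage.gaussian_filter(z, sigma=config.correlation_length_px / 2.0,
                                        mode="wrap")
            z = z / max(z.std(), 1e-12)
        agb = agb * np.exp(sigma * z - sigma ** 2 / 2)
    return agb


def _place_plots(config: SceneConfig, rng) -> list:
    """Stratified random plot placement: plots are spread over treatment
    blocks on a grid of candidate cells one coarse pixel wide, guaranteeing
    a minimum separation of one coarse pixel."""
    _, labels, slices = treatment_blocks(config)
    n_blocks = len(slices)
    base, extra = divmod(config.n_plots, n_blocks)
    counts = [base + (1 if i < extra else 0) for i in range(n_blocks)]
    sep = config.factor
    positions = []
    for count, sl in zip(counts, slices):
        rows = np.arange(sl[0].start, sl[0].stop)
        cols = np.arange(sl[1].start, sl[1].stop)
        # candidate cell centres, one coarse-pixel apart
        rc = np.arange(rows[0] + sep // 2, rows[-1] - sep // 2 + 1, sep)
        cc = np.arange(cols[0] + sep // 2, cols[-1] - sep // 2 + 1, sep)
        cells = [(r, c) for r in rc for c in cc]
        if len(cells) < count:
            raise ValueError(f"block too small for {count} plots at separation {sep}")
        chosen = rng.choice(len(cells), size=count, replace=False)
        positions.extend(cells[i] for i in chosen)
    return positions


def _footprint_mean(arr: np.ndarray, row: int, col: int, half_px: int) -> float:
    return float(arr[row - half_px + 1:row + half_px + 1,
                     col - half_px + 1:col + half_px + 1].mean())


@dataclass
class SyntheticScene:
    """A complete rendered study scene (all rasters share one
    geotransform family: coarse footprint = factor x fine footprint)."""

    lai: Raster                 # fine, m2/m2
    agb: Raster                 # fine, g/m2
    uav_cube: Raster            # (bands, rows, cols) reflectance
    satellite: Raster           # (4, rows/f, cols/f) reflectance
    plots: list
    treatment_raster: Raster    # int block labels
    treatment_labels: list
    config: SceneConfig
    grid: SpectralGrid
    srf: SensorSRF

    @property
    def provenance(self) -> dict:
        return make_provenance(self.config.to_dict(), seed=self.config.seed)


def render_scene(config: SceneConfig, forward_model=None, srf: SensorSRF | None = None,
                 leaf=None, soil=None) -> SyntheticScene:
    """Render the full scene: LAI/AGB fields, UAV cube (forward model per
    fine pixel + additive noise), satellite image (SRF convolution of the
    fine spectra, block-aggregated, + noise) and noisy plot samples."""
    rng_field, rng_agb, rng_uav, rng_sat, rng_plots, rng_soil = _child_rngs(config.seed, 6)
    model = forward_model or BeerLambertCanopy()
    grid = SpectralGrid(np.linspace(400.0, 1000.0, config.spectral_bands))
    srf = srf or gf2_srf(grid)
    if srf.grid.n_bands != grid.n_bands or not np.allclose(
            srf.grid.wavelengths_nm, grid.wavelengths_nm):
        raise ValueError("sensor SRF is not defined on the forward model's spectral grid")
    leaf = default_leaf_spectrum(grid) if leaf is None else np.asarray(leaf, dtype=float)
    soil = default_soil_spectrum(grid) if soil is None else np.asarray(soil, dtype=float)

    lai = generate_lai_field(config, rng_field)
    agb = lai_to_agb(lai, config, rng_agb)

    # soil-background brightness field: a patch-correlated confounder seen
    # through the canopy gaps (the LUT treats it as a nuisance parameter)
    s_lo, s_hi = config.soil_scale_range
    if s_hi > s_lo:
        z = ndimage.gaussian_filter(
            rng_soil.standard_normal(config.shape),
            sigma=config.correlation_length_px * config.soil_correlation_factor / 2.0,
            mode="wrap")
        zmin, zmax = z.min(), z.max()
        u = (z - zmin) / (zmax - zmin) if zmax > zmin else np.full_like(z, 0.5)
        soil_field = s_lo + (s_hi - s_lo) * u
    else:
        soil_field = np.full(config.shape, s_lo)

    # forward model per fine pixel (vectorized for the built-in model)
    cos_t = np.cos(np.radians(config.sun_zenith_deg))
    p = np.exp(-config.g * lai / cos_t)
    cube = (leaf[:, None, None] * (1.0 - p)[None]
            + np.clip(soil[:, None, None] * soil_field[None], 0.0, 1.0) * p[None])
    cube = cube.astype(np.float32)
    sat_clean = convolve_srf(cube, srf)  # (4, rows, cols) on the fine grid
    if config.reflectance_noise_sd > 0:
        cube = cube + rng_uav.normal(0.0, config.reflectance_noise_sd,
                                     size=cube.shape).astype(np.float32)
    cube = np.clip(cube, 0.0, 1.0)

    f = config.factor
    nrc, ncc = config.coarse_shape
    sat = sat_clean.reshape(4, nrc, f, ncc, f).mean(axis=(2, 4))
    if config.reflectance_noise_sd > 0:
        sat = sat + rng_sat.normal(0.0, config.reflectance_noise_sd, size=sat.shape)
    sat = np.clip(sat, 0.0, 1.0)

    fine_meta = config.fine_meta()
    treat_raster, labels, _ = treatment_blocks(config)

    half_px = int(round(config.plot_esu_m / config.fine_pixel_m / 2))
    plots = []
    for i, (r, c) in enumerate(_place_plots(config, rng_plots)):
        # plot centre on the pixel-corner between the 2h x 2h footprint
        x = (c + 0.5) * config.fine_pixel_m
        y = fine_meta.origin_y - (r + 0.5) * config.fine_pixel_m
        agb_true = _footprint_mean(agb, r, c, half_px)
        lai_true = _footprint_mean(lai, r, c, half_px)
        sd = config.plot_noise_sd_frac
        agb_obs = max(0.0, agb_true * (1 + sd * rng_plots.standard_normal())) if sd else agb_true
        lai_obs = max(0.0, lai_true * (1 + sd * rng_plots.standard_normal())) if sd else lai_true
        plots.append(PlotSample(f"P{i + 1:03d}", float(x), float(y),
                                agb_obs, lai_obs, esu_m=config.plot_esu_m))

    prov = make_provenance(config.to_dict(), seed=config.seed)
    from dataclasses import replace
    cube_meta = replace(fine_meta, units="reflectance",
                        wavelengths_nm=tuple(grid.wavelengths_nm))
    sat_meta = replace(fine_meta.coarsened(f), units="reflectance",
                       band_names=srf.band_names)
    return SyntheticScene(
        lai=Raster(lai, fine_meta, prov),
        agb=Raster(agb, replace(fine_meta, units="g/m2"), prov),
        uav_cube=Raster(cube, cube_meta, prov),
        satellite=Raster(sat, sat_meta, prov),
        plots=plots,
        treatment_raster=Raster(treat_raster, replace(fine_meta, units="label"), prov),
        treatment_labels=labels,
        config=config,
        grid=grid,
        srf=srf,
    )


def write_scene(scene: SyntheticScene, out_dir) -> dict:
    """Persist a scene: TIFF rasters, ENVI-style UAV cube, CSV plot table
    and a JSON provenance sidecar.  Returns the path map."""
    import json
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = scene.provenance
    paths = {
        "lai": out / "fine_lai.tif",
        "agb": out / "fine_agb.tif",
        "satellite": out / "satellite.tif",
        "uav_cube": out / "uav_cube.bsq",
        "plots": out / "plots.csv",
        "provenance": out / "provenance.json",
    }
    write_raster(paths["lai"], scene.lai, prov)
    write_raster(paths["agb"], scene.agb, prov)
    write_raster(paths["satellite"], scene.satellite, prov)
    write_cube(paths["uav_cube"], scene.uav_cube, prov)
    write_plots(paths["plots"], scene.plots, prov)
    paths["provenance"].write_text(json.dumps(
        {"config": scene.config.to_dict(), "provenance": prov}, indent=1, default=str))
    return {k: str(v) for k, v in paths.items()}
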