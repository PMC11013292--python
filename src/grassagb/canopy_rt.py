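"""Forward canopy reflectance simulation, sensor band convolution and
look-up-table (LUT) construction.

The forward model is pluggable: any callable object implementing
``simulate(state, grid) -> spectrum`` can stand behind the LUT builder
(e.g. an external PROSAIL binding).  The tested default is a Beer-Lambert
gap-fraction mixing model,

    rho(lambda) = (1 - P) * rho_leaf(lambda) + P * rho_soil(lambda),
    P = exp(-G * LAI / cos(theta_s)),

where P is the canopy gap fraction, G the mean leaf projection
coefficient (0.5 = spherical leaf angle distribution) and theta_s the sun
zenith angle.  The model is monotone in LAI toward the leaf spectrum
wherever leaf and soil reflectance differ, which makes LUT inversion
well-posed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geo_io import make_provenance

__all__ = [
    "SpectralGrid",
    "CanopyState",
    "BeerLambertCanopy",
    "SensorSRF",
    "LUTTable",
    "default_uav_grid",
    "default_leaf_spectrum",
    "default_soil_spectrum",
    "simulate_reflectance",
    "convolve_srf",
    "gf2_srf",
    "HyperspectralFeatures",
    "SensorBandFeatures",
    "draw_lut_spectra",
    "build_lut",
    "GF2_BAND_RANGES_NM",
]

log = logging.getLogger("grassagb")

#: GF-2 PMS multispectral band ranges (nm); the true response curves are not
#: published, so unit-weight boxcars over these intervals are the default SRF.
GF2_BAND_RANGES_NM = {
    "blue": (450.0, 520.0),
    "green": (520.0, 590.0),
    "red": (630.0, 690.0),
    "nir": (770.0, 890.0),
}


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength grid (nm), within 350-2500 nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectral grid needs a 1-D wavelength vector")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 350 or wl[-1] > 2500:
            raise ValueError("wavelengths must lie within 350-2500 nm")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid band nearest the requested wavelength."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


def default_uav_grid() -> SpectralGrid:
    """The 270-band 400-1000 nm VNIR grid of the emulated push-broom
    hyperspectral camera."""
    return SpectralGrid(np.linspace(400.0, 1000.0, 270))


def _gauss(wl, centre, width):
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def default_leaf_spectrum(grid: SpectralGrid) -> np.ndarray:
    """Synthetic green-leaf reflectance: blue/red chlorophyll absorption,
    green bump near 550 nm, logistic red edge onto an NIR plateau."""
    wl = grid.wavelengths_nm
    base = 0.05 + 0.07 * _gauss(wl, 550.0, 28.0)
    red_edge = 0.43 / (1.0 + np.exp(-(wl - 718.0) / 16.0))
    return np.clip(base + red_edge, 0.0, 1.0)


def default_soil_spectrum(grid: SpectralGrid) -> np.ndarray:
    """Synthetic dry-soil reflectance: featureless, brightening with
    wavelength."""
    wl = grid.wavelengths_nm
    return np.clip(0.10 + 0.18 * (wl - 400.0) / 600.0, 0.0, 1.0)


@dataclass
class CanopyState:
    """State vector of the built-in forward model.

    ``extra`` is an opaque parameter mapping passed through to external
    forward models (e.g. PROSAIL leaf biochemistry)."""

    lai: float
    leaf_reflectance: np.ndarray
    soil_reflectance: np.ndarray
    g: float = 0.5
    sun_zenith_deg: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lai < 0:
            raise ValueError("LAI must be >= 0")
        if not (0 <= self.sun_zenith_deg < 90):
            raise ValueError("sun zenith must be in [0, 90) degrees")
        for name in ("leaf_reflectance", "soil_reflectance"):
            spec = np.asarray(getattr(self, name), dtype=float)
            if spec.min() < 0 or spec.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, spec)


class BeerLambertCanopy:
    """Two-stream Beer-Lambert mixing model (see module docstring)."""

    name = "beer-lambert"

    def gap_fraction(self, lai: float, g: float, sun_zenith_deg: float) -> float:
        return float(np.exp(-g * lai / np.cos(np.radians(sun_zenith_deg))))

    def simulate(self, state: CanopyState, grid: SpectralGrid) -> np.ndarray:
        if state.leaf_reflectance.shape != grid.wavelengths_nm.shape:
            raise ValueError("leaf spectrum is not on the simulation grid")
        if state.soil_reflectance.shape != grid.wavelengths_nm.shape:
            raise ValueError("soil spectrum is not on the simulation grid")
        p = self.gap_fraction(state.lai, state.g, state.sun_zenith_deg)
        return (1.0 - p) * state.leaf_reflectance + p * state.soil_reflectance


def simulate_reflectance(state: CanopyState, grid: SpectralGrid, model=None) -> np.ndarray:
    """Canopy reflectance spectrum for a state; defaults to the built-in
    Beer-Lambert model."""
    model = model or BeerLambertCanopy()
    return model.simulate(state, grid)


# ---------------------------------------------------------------------------
# sensor spectral response
# ---------------------------------------------------------------------------

@dataclass
class SensorSRF:
    """Per-band wavelength weighting on a spectral grid.

    ``weights`` has shape (n_out_bands, n_grid_bands); each row is
    normalized to sum to one."""

    grid: SpectralGrid
    band_names: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape != (len(self.band_names), self.grid.n_bands):
            raise ValueError("weights must be (n_bands, n_grid_bands)")
        if np.any(w < 0):
            raise ValueError("SRF weights must be >= 0")
        sums = w.sum(axis=1)
        if np.any(sums <= 0):
            bad = [self.band_names[i] for i in np.nonzero(sums <= 0)[0]]
            raise ValueError(f"SRF bands with empty support: {bad}")
        self.weights = w / sums[:, None]
        self.band_names = tuple(self.band_names)

    @classmethod
    def boxcar(cls, grid: SpectralGrid, band_ranges: dict) -> "SensorSRF":
        """Unit-weight boxcar SRFs over [lo, hi] nm intervals."""
        wl = grid.wavelengths_nm
        names, rows = [], []
        for name, (lo, hi) in band_ranges.items():
            if hi < wl[0] or lo > wl[-1]:
                raise ValueError(f"band {name} [{lo}, {hi}] nm outside the spectral grid")
            names.append(name)
            rows.append(((wl >= lo) & (wl <= hi)).astype(float))
        return cls(grid, tuple(names), np.array(rows))

    @classmethod
    def from_csv(cls, path, grid: SpectralGrid) -> "SensorSRF":
        """Read (band, wavelength_nm, weight) rows; weights are linearly
        interpolated onto ``grid`` then renormalized."""
        per_band: dict[str, list] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                per_band.setdefault(row["band"].strip(), []).append(
                    (float(row["wavelength_nm"]), float(row["weight"])))
        names, rows = [], []
        for name, pairs in per_band.items():
            pairs.sort()
            wl_in = np.array([p[0] for p in pairs])
            w_in = np.array([p[1] for p in pairs])
            names.append(name)
            rows.append(np.interp(grid.wavelengths_nm, wl_in, w_in, left=0.0, right=0.0))
        return cls(grid, tuple(names), np.array(rows))

    def band_index(self, name: str) -> int:
        return self.band_names.index(name)


def gf2_srf(grid: SpectralGrid) -> SensorSRF:
    """Default 4-band boxcar SRF for the GF-2 PMS multispectral sensor."""
    return SensorSRF.boxcar(grid, GF2_BAND_RANGES_NM)


def convolve_srf(spectrum: np.ndarray, srf: SensorSRF) -> np.ndarray:
    """Reduce spectra to sensor bands: each band is the normalized-weight
    average of the spectrum.  ``spectrum`` may be (n_wl,), (n, n_wl) or a
    cube (n_wl, rows, cols); the wavelength axis must match the SRF grid."""
    spec = np.asarray(spectrum, dtype=float)
    n_wl = srf.grid.n_bands
    if spec.ndim == 1:
        if spec.size != n_wl:
            raise ValueError("spectrum is not on the SRF grid")
        return srf.weights @ spec
    if spec.ndim == 2:
        if spec.shape[1] != n_wl:
            raise ValueError("spectra are not on the SRF grid")
        return spec @ srf.weights.T
    if spec.ndim == 3:
        if spec.shape[0] != n_wl:
            raise ValueError("cube wavelength axis is not on the SRF grid")
        return np.tensordot(srf.weights, spec, axes=(1, 0))
    raise ValueError("spectrum must be 1-D, 2-D or 3-D")


# ---------------------------------------------------------------------------
# feature extraction and LUT construction
# ---------------------------------------------------------------------------

def _ndvi(nir, red):
    return (nir - red) / (nir + red)


def _osavi(nir, red):
    return 1.16 * (nir - red) / (nir + red + 0.16)


@dataclass
class HyperspectralFeatures:
    """Feature spec for hyperspectral inversion: reflectance at selected
    sensitive wavelengths plus NDVI and OSAVI from a (red, nir) pair."""

    grid: SpectralGrid
    sensitive_wavelengths_nm: tuple
    red_nm: float = 670.0
    nir_nm: float = 800.0

    @property
    def names(self) -> tuple:
        return tuple(f"rho{w:.0f}" for w in self.sensitive_wavelengths_nm) + ("NDVI", "OSAVI")

    def from_spectra(self, spectra: np.ndarray) -> np.ndarray:
        """(n, n_wl) spectra -> (n, n_features)."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if spectra.shape[1] != self.grid.n_bands:
            raise ValueError("spectra are not on the feature grid")
        idx = [self.grid.index_of(w) for w in self.sensitive_wavelengths_nm]
        red = spectra[:, self.grid.index_of(self.red_nm)]
        nir = spectra[:, self.grid.index_of(self.nir_nm)]
        return np.column_stack([spectra[:, i] for i in idx] + [_ndvi(nir, red), _osavi(nir, red)])


@dataclass
class SensorBandFeatures:
    """Feature spec for multispectral inversion: all sensor bands plus NDVI
    and OSAVI from named red/NIR bands."""

    srf: SensorSRF
    red_band: str = "red"
    nir_band: str = "nir"

    @property
    def names(self) -> tuple:
        return self.srf.band_names + ("NDVI", "OSAVI")

    def from_spectra(self, spectra: np.ndarray) -> np.ndarray:
        return self.from_bands(convolve_srf(np.atleast_2d(spectra), self.srf))

    def from_bands(self, bands: np.ndarray) -> np.ndarray:
        """(n, n_sensor_bands) band reflectances -> (n, n_features)."""
        bands = np.atleast_2d(np.asarray(bands, dtype=float))
        red = bands[:, self.srf.band_index(self.red_band)]
        nir = bands[:, self.srf.band_index(self.nir_band)]
        return np.column_stack([bands, _ndvi(nir, red), _osavi(nir, red)])


@dataclass
class LUTTable:
    """Forward-simulated parameter/feature pairs for inversion.

    Entries keep insertion order (the seeded draw order); cost ties during
    inversion are broken by the lowest entry index."""

    lai: np.ndarray
    params: dict
    features: np.ndarray
    feature_names: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lai = np.asarray(self.lai, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if self.lai.size < 1:
            raise ValueError("LUT must have at least one entry")
        if self.features.shape != (self.lai.size, len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("LUT features must be finite")

    @property
    def n(self) -> int:
        return self.lai.size

    def feature_column(self, name: str) -> np.ndarray:
        return self.features[:, self.feature_names.index(name)]

    def lai_grid_spacing(self) -> float:
        """Largest gap between consecutive sorted LAI entries — the
        effective resolution of LUT inversion in LAI."""
        srt = np.sort(self.lai)
        return float(np.max(np.diff(srt))) if srt.size > 1 else 0.0


#: Default free-parameter ranges for LUT draws: LAI plus a soil-brightness
#: nuisance (soil background varies strongly across a patchy steppe, whereas
#: the leaf spectrum is field-calibrated by ground spectroscopy and held
#: fixed).
DEFAULT_LUT_RANGES = {
    "lai": (0.0, 6.0),
    "soil_scale": (0.6, 1.4),
}


def draw_lut_spectra(n, ranges, grid: SpectralGrid, seed, model=None,
                     leaf=None, soil=None, g=0.5, sun_zenith_deg=0.0):
    """Seeded forward-simulation draws for LUT construction.

    Free parameters (uniform per range): ``lai`` plus optional ``leaf_scale``
    and ``soil_scale`` brightness multipliers on the base spectra.  Returns
    (draws dict, (n, n_wl) spectra)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or BeerLambertCanopy()
    leaf = default_leaf_spectrum(grid) if leaf is None else np.asarray(leaf, dtype=float)
    soil = default_soil_spectrum(grid) if soil is None else np.asarray(soil, dtype=float)
    unknown = set(ranges) - {"lai", "leaf_scale", "soil_scale"}
    if unknown:
        raise ValueError(f"unsupported LUT parameters: {sorted(unknown)}")
    if "lai" not in ranges:
        raise ValueError("LUT ranges must include 'lai'")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in ("lai", "leaf_scale", "soil_scale"):
        lo, hi = ranges.get(name, (1.0, 1.0))
        draws[name] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    if draws["lai"].min() < 0:
        raise ValueError("LAI range must be >= 0")

    cos_t = np.cos(np.radians(sun_zenith_deg))
    p = np.exp(-g * draws["lai"] / cos_t)  # gap fraction per entry
    leaf_spec = np.clip(draws["leaf_scale"][:, None] * leaf[None, :], 0.0, 1.0)
    soil_spec = np.clip(draws["soil_scale"][:, None] * soil[None, :], 0.0, 1.0)
    if isinstance(model, BeerLambertCanopy):
        spectra = (1.0 - p[:, None]) * leaf_spec + p[:, None] * soil_spec
    else:  # external forward model: one simulate() call per entry
        spectra = np.empty((n, grid.n_bands))
        for i in range(n):
            state = CanopyState(draws["lai"][i], leaf_spec[i], soil_spec[i],
                                g=g, sun_zenith_deg=sun_zenith_deg)
            spectra[i] = model.simulate(state, grid)
    return draws, spectra


def build_lut(n, ranges, feature_spec, grid: SpectralGrid, seed,
              model=None, leaf=None, soil=None, g=0.5, sun_zenith_deg=0.0) -> LUTTable:
    """Build an inversion LUT from ``n`` seeded uniform parameter draws
    (see :func:`draw_lut_spectra`), reduced to the feature spec.  The
    default workflow uses ``n = 100_000`` forward simulations; pipelines
    running at desk scale pass a smaller ``n``."""
    model = model or BeerLambertCanopy()
    draws, spectra = draw_lut_spectra(n, ranges, grid, seed, model=model, leaf=leaf,
                                      soil=soil, g=g, sun_zenith_deg=sun_zenith_deg)
    features = feature_spec.from_spectra(spectra)
    prov = make_provenance({"ranges": {k: list(v) for k, v in ranges.items()},
                            "model": getattr(model, "name", type(model).__name__),
                            "n": n}, seed=seed)
    return LUTTable(draws["lai"], draws, features, tuple(feature_spec.names), prov)
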