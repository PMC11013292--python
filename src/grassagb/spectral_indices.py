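"""Vegetation indices and band optimization.

Six two-band indices are supported, written in terms of the reflectances
rho_i (reference band, usually red/visible) and rho_j (usually NIR):

    RVI   = rho_j / rho_i
    NDVI  = (rho_j - rho_i) / (rho_i + rho_j)
    RDVI  = (rho_j - rho_i) / sqrt(rho_i + rho_j)
    OSAVI = (1 + 0.16) (rho_j - rho_i) / (rho_i + rho_j + 0.16)
    MSAVI = (2 rho_j + 1 - sqrt((2 rho_j + 1)^2 - 8 (rho_j - rho_i))) / 2
    CI    = rho_j / rho_i - 1

RDVI and MSAVI follow their standard literature forms.  Band-pair
optimization evaluates a chosen index for every ordered wavelength pair of
a hyperspectral cube at the ground-plot footprints and ranks pairs by the
Pearson correlation with measured AGB; sensitive-band selection ranks
individual bands by |Pearson r| against LAI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geo_io import Raster, PlotSample

__all__ = [
    "VI_NAMES",
    "VIDefinition",
    "vi_formula",
    "compute_vi",
    "plot_footprint_means",
    "optimize_band_pair",
    "select_sensitive_bands",
    "BandPairCorrelationMatrix",
]

log = logging.getLogger("grassagb")

VI_NAMES = ("RVI", "NDVI", "RDVI", "OSAVI", "MSAVI", "CI")

#: Reference band pairs (wavelength_i, wavelength_j in nm) from a meadow-steppe
#: hyperspectral campaign; pass as ``PipelineConfig.vi_pairs`` to skip the
#: exhaustive search when reproducing that configuration.
REFERENCE_VI_PAIRS = {
    "RVI": (644.0, 544.0),
    "NDVI": (673.0, 935.0),
    "RDVI": (684.0, 522.0),
    "OSAVI": (673.0, 935.0),
    "MSAVI": (684.0, 522.0),
    "CI": (644.0, 544.0),
}


def _rvi(i, j):
    return j / i


def _ndvi(i, j):
    return (j - i) / (i + j)


def _rdvi(i, j):
    return (j - i) / np.sqrt(i + j)


def _osavi(i, j):
    return 1.16 * (j - i) / (i + j + 0.16)


def _msavi(i, j):
    return (2 * j + 1 - np.sqrt((2 * j + 1) ** 2 - 8 * (j - i))) / 2


def _ci(i, j):
    return j / i - 1


_FORMULAS = {"RVI": _rvi, "NDVI": _ndvi, "RDVI": _rdvi,
             "OSAVI": _osavi, "MSAVI": _msavi, "CI": _ci}

#: denominator of each index, for zero-denominator nodata handling
_DENOMS = {
    "RVI": lambda i, j: i,
    "NDVI": lambda i, j: i + j,
    "RDVI": lambda i, j: i + j,
    "OSAVI": lambda i, j: i + j + 0.16,
    "MSAVI": lambda i, j: np.ones_like(i),
    "CI": lambda i, j: i,
}


def vi_formula(name: str):
    """The closed-form index function ``f(rho_i, rho_j)``."""
    try:
        return _FORMULAS[name]
    except KeyError:
        raise ValueError(f"unknown VI {name!r}; supported: {VI_NAMES}") from None


@dataclass(frozen=True)
class VIDefinition:
    """A named index bound to two bands, each given as a wavelength (nm,
    resolved to the nearest cube band) or an integer band index."""

    name: str
    band_i: float
    band_j: float

    def __post_init__(self):
        vi_formula(self.name)
        if self.band_i == self.band_j:
            raise ValueError("band roles i and j must differ")


def _resolve_band(image: Raster, band) -> int:
    wl = image.meta.wavelengths_nm
    names = image.meta.band_names
    if isinstance(band, str):
        if band not in names:
            raise ValueError(f"band {band!r} not in {names}")
        return names.index(band)
    if isinstance(band, (int, np.integer)) and not wl:
        return int(band)
    if wl:
        return int(np.argmin(np.abs(np.asarray(wl) - float(band))))
    return int(band)


def compute_vi(image: Raster, vi: VIDefinition) -> Raster:
    """Per-pixel evaluation of an index on a multiband raster; pixels with a
    zero denominator (or nodata input) become NaN and are counted."""
    if image.data.ndim != 3:
        raise ValueError("compute_vi needs a multiband raster")
    bi, bj = _resolve_band(image, vi.band_i), _resolve_band(image, vi.band_j)
    rho_i = np.asarray(image.data[bi], dtype=float)
    rho_j = np.asarray(image.data[bj], dtype=float)
    nodata = image.meta.nodata
    invalid = ~np.isfinite(rho_i) | ~np.isfinite(rho_j)
    if np.isfinite(nodata):
        invalid |= (rho_i == nodata) | (rho_j == nodata)
    denom = _DENOMS[vi.name](rho_i, rho_j)
    zero_den = np.isclose(denom, 0.0) & ~invalid
    if zero_den.any():
        log.warning("compute_vi(%s): %d pixels with zero denominator set to nodata",
                    vi.name, int(zero_den.sum()))
    bad = invalid | zero_den
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vi_formula(vi.name)(rho_i, rho_j)
    out = np.where(bad, np.nan, out)
    meta = image.meta
    from dataclasses import replace
    out_meta = replace(meta, band_names=(), wavelengths_nm=(), nodata=float("nan"),
                       units="reflectance")
    return Raster(out, out_meta, image.provenance)


# ---------------------------------------------------------------------------
# plot extraction and correlation search
# ---------------------------------------------------------------------------

def plot_footprint_means(cube: Raster, plots) -> np.ndarray:
    """Mean spectrum over each plot's ESU footprint: all fine pixels whose
    centres fall inside the square footprint (pixel-centre convention).

    Returns (n_plots, n_bands)."""
    if cube.data.ndim != 3:
        raise ValueError("need a multiband cube")
    meta = cube.meta
    nb, nr, nc = cube.data.shape
    out = np.empty((len(plots), nb))
    col_x = meta.origin_x + np.arange(nc) * meta.pixel_x
    row_y = meta.origin_y - np.arange(nr) * meta.pixel_y
    for k, p in enumerate(plots):
        half = p.esu_m / 2.0
        cols = np.nonzero((col_x >= p.x - half) & (col_x <= p.x + half))[0]
        rows = np.nonzero((row_y >= p.y - half) & (row_y <= p.y + half))[0]
        if cols.size == 0 or rows.size == 0:
            raise ValueError(f"plot {p.plot_id} footprint lies outside the cube")
        block = cube.data[:, rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        out[k] = np.nanmean(block.reshape(nb, -1), axis=1)
    return out


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of x against y; zero-variance columns -> NaN."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    return r


@dataclass
class BandPairCorrelationMatrix:
    """Full ordered-band-pair Pearson-R search result for one index.

    ``r[a, b]`` is the correlation between VI(band a as i, band b as j) and
    plot AGB; the diagonal and undefined (zero-variance) cells are NaN with
    ``undefined`` set."""

    vi_name: str
    wavelengths_nm: np.ndarray
    r: np.ndarray
    n: int
    undefined: np.ndarray = field(default=None)
    best_pair: tuple = ()
    best_r: float = float("nan")

    @property
    def best_indices(self) -> tuple:
        a = int(np.argmin(np.abs(self.wavelengths_nm - self.best_pair[0])))
        b = int(np.argmin(np.abs(self.wavelengths_nm - self.best_pair[1])))
        return a, b


def optimize_band_pair(cube: Raster, plots, vi_name: str,
                       use_abs: bool = False) -> BandPairCorrelationMatrix:
    """Exhaustive ordered band-pair search maximizing the Pearson R between
    the index at plot footprints and measured AGB.

    By default the *maximum R* (signed) selects the pair; ``use_abs``
    switches to max |R|.  Ties break to the lexicographically smallest
    (wavelength_i, wavelength_j)."""
    agb = np.array([p.agb_g_m2 for p in plots], dtype=float)
    if agb.size < 3:
        raise ValueError("need at least 3 plots")
    spectra = plot_footprint_means(cube, plots)  # (n_plots, K)
    if not np.all(np.isfinite(spectra)):
        raise ValueError("non-finite plot spectra")
    wl = np.asarray(cube.meta.wavelengths_nm, dtype=float)
    if wl.size != spectra.shape[1]:
        wl = np.arange(spectra.shape[1], dtype=float)
    K = spectra.shape[1]
    formula = vi_formula(vi_name)
    r = np.full((K, K), np.nan)
    for a in range(K):  # band a plays role i
        rho_i = spectra[:, a][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            vi_vals = formula(rho_i, spectra)  # (n_plots, K), column b = role j
        vi_vals = np.where(np.isfinite(vi_vals), vi_vals, np.nan)
        valid = ~np.isnan(vi_vals).any(axis=0)
        rr = np.full(K, np.nan)
        if valid.any():
            rr[valid] = _pearson_columns(vi_vals[:, valid], agb)
        r[a] = rr
    np.fill_diagonal(r, np.nan)
    undefined = np.isnan(r)
    if undefined.all():
        result = BandPairCorrelationMatrix(vi_name, wl, r, int(agb.size), undefined)
        log.warning("optimize_band_pair(%s): correlation undefined for every pair", vi_name)
        return result
    score = np.abs(r) if use_abs else r
    best = np.nanmax(score)
    cand = np.argwhere(np.isclose(score, best, rtol=0, atol=1e-15))
    # lexicographic tie-break on (wavelength_i, wavelength_j)
    order = np.lexsort((wl[cand[:, 1]], wl[cand[:, 0]]))
    a, b = cand[order[0]]
    return BandPairCorrelationMatrix(vi_name, wl, r, int(agb.size), undefined,
                                     best_pair=(float(wl[a]), float(wl[b])),
                                     best_r=float(r[a, b]))


def select_sensitive_bands(reflectance: np.ndarray, lai: np.ndarray, count: int = 5,
                           wavelengths_nm=None) -> list:
    """Rank bands by |Pearson r| between per-band reflectance and LAI and
    return the top ``count`` wavelengths (descending |r|; ties by ascending
    wavelength; undefined/constant bands rank last).

    ``reflectance`` is (n_samples, n_bands) — e.g. LUT spectra or plot
    footprint spectra."""
    x = np.asarray(reflectance, dtype=float)
    y = np.asarray(lai, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("reflectance must be (n_samples, n_bands) matching lai")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    K = x.shape[1]
    if not (1 <= count <= K):
        raise ValueError(f"count must be in [1, {K}]")
    wl = (np.arange(K, dtype=float) if wavelengths_nm is None
          else np.asarray(wavelengths_nm, dtype=float))
    r = np.abs(_pearson_columns(x, y))
    rank_key = np.where(np.isnan(r), -np.inf, r)
    order = np.lexsort((wl, -rank_key))  # descending |r|, ties by ascending wavelength
    return [float(wl[i]) for i in order[:count]]
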