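"""LAI retrieval and spatial scale-effect correction.

Retrieval is LUT-based: the cost of a LUT entry is the RMSE between the
observed feature vector and the entry's simulated features, and the
retrieved LAI is the mean LAI of the ``q`` best entries.

Because a retrieval applied to a coarse pixel's *mean* signal differs from
the mean of fine-pixel retrievals whenever the retrieval function is
nonlinear, a per-coarse-pixel spatial effect factor

    k = f(NIR_m, R_m) - (1/n) sum_i f(NIR_i, R_i)
      ~ -1/2 [ f_NN VAR_NIR + f_RR VAR_R + 2 f_NR COV_NIR,R ]

is computed by second-order Taylor expansion of the semi-empirical
retrieval surrogate f(NIR, R) = g(NDVI) around the footprint means, using
the within-footprint variances and covariance of the NIR and red bands
(population, 1/n normalization — the normalization the Taylor derivation
assumes).  k is exact for any f quadratic in (NIR, R).

The factor enters a modified inversion cost

    delta = (1/n) sum_b (rho_obs_b - rho_sim_b)^2 / eps_b
            + (LAI - k - LAI_e)^2 / eps_LAI,

whose prior term anchors the (coarse-scale-consistent) candidate LAI to
the expected true mean LAI_e shifted by k.  ``retrieve_lai_corrected``
composes the full correction: plain inversion -> LAI_e -> modified
inversion -> subtract k to return to the true (fine-mean) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .canopy_rt import LUTTable

__all__ = [
    "invert_lai_lut",
    "SemiEmpiricalLAIFn",
    "fit_semiempirical_g",
    "QuadraticFn",
    "NumericalBivariateFn",
    "WindowMoments",
    "windowed_moments",
    "ScaleFactorMap",
    "compute_k",
    "ScaledInversionConfig",
    "invert_lai_scaled",
    "retrieve_lai_corrected",
]

log = logging.getLogger("grassagb")

_CHUNK_ELEMS = 2e7  # cost-tensor elements per inversion chunk (memory bound)


def _chunk_size(n_lut: int, n_feat: int) -> int:
    return max(1, int(_CHUNK_ELEMS // max(1, n_lut * n_feat)))


def invert_lai_lut(observed: np.ndarray, lut: LUTTable, q: int = 1):
    """LUT inversion by feature-RMSE minimization.

    ``observed``: (n_features,) for one pixel or (n_pixels, n_features).
    Returns the mean LAI of the ``q`` lowest-cost entries (ties broken by
    lowest entry index).  Pixels with non-finite features return NaN and
    are counted in the log."""
    if lut.n == 0:
        raise ValueError("empty LUT")
    if q < 1:
        raise ValueError("q must be >= 1")
    obs = np.asarray(observed, dtype=float)
    single = obs.ndim == 1
    obs = np.atleast_2d(obs)
    if obs.shape[1] != lut.features.shape[1]:
        raise ValueError("observation does not match the LUT feature spec")
    n_pix = obs.shape[0]
    out = np.full(n_pix, np.nan)
    finite = np.all(np.isfinite(obs), axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        log.warning("invert_lai_lut: %d non-finite observations rejected", n_bad)
    feats = lut.features
    q_eff = min(q, lut.n)
    idx_finite = np.nonzero(finite)[0]
    chunk = _chunk_size(lut.n, feats.shape[1])
    for start in range(0, idx_finite.size, chunk):
        sel = idx_finite[start:start + chunk]
        # squared-error cost; RMSE is monotone in it so the argmin agrees
        cost = ((obs[sel][:, None, :] - feats[None, :, :]) ** 2).mean(axis=2)
        if q_eff == 1:
            out[sel] = lut.lai[np.argmin(cost, axis=1)]  # argmin takes lowest index on ties
        else:
            part = np.argpartition(cost, q_eff - 1, axis=1)[:, :q_eff]
            for row, pix in enumerate(sel):
                cand = part[row]
                cand = cand[np.lexsort((cand, cost[row, cand]))]
                out[pix] = lut.lai[cand].mean()
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# semi-empirical g(NDVI) and its chain-rule partials
# ---------------------------------------------------------------------------

@dataclass
class SemiEmpiricalLAIFn:
    """Twice-differentiable surrogate LAI = g(NDVI) = f(NIR, R).

    ``coeffs`` are polynomial coefficients of g in ascending degree.  All
    partials of f are obtained analytically through the chain rule via
    v = NDVI(NIR, R) = (NIR - R)/(NIR + R):

        v_N = 2R/s^2,   v_R = -2N/s^2,          s = NIR + R
        v_NN = -4R/s^3, v_RR = 4N/s^3, v_NR = 2(N - R)/s^3
    """

    coeffs: np.ndarray
    ndvi_domain: tuple = (-1.0, 1.0)
    fit_rmse: float = float("nan")

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)

    def g(self, ndvi):
        return np.polynomial.polynomial.polyval(np.asarray(ndvi, dtype=float), self.coeffs)

    def dg(self, ndvi):
        return np.polynomial.polynomial.polyval(
            np.asarray(ndvi, dtype=float), np.polynomial.polynomial.polyder(self.coeffs))

    def d2g(self, ndvi):
        return np.polynomial.polynomial.polyval(
            np.asarray(ndvi, dtype=float), np.polynomial.polynomial.polyder(self.coeffs, 2))

    # --- f(NIR, R) and partials ---

    def __call__(self, nir, r):
        return self.f(nir, r)

    def f(self, nir, r):
        nir, r = np.asarray(nir, dtype=float), np.asarray(r, dtype=float)
        return self.g((nir - r) / (nir + r))

    def grad(self, nir, r):
        nir, r = np.asarray(nir, dtype=float), np.asarray(r, dtype=float)
        s = nir + r
        v = (nir - r) / s
        dg = self.dg(v)
        return dg * 2 * r / s ** 2, dg * (-2 * nir / s ** 2)

    def hessian(self, nir, r):
        """(f_NN, f_RR, f_NR) at (nir, r); inputs broadcast."""
        nir, r = np.asarray(nir, dtype=float), np.asarray(r, dtype=float)
        s = nir + r
        v = (nir - r) / s
        dg, d2g = self.dg(v), self.d2g(v)
        v_n = 2 * r / s ** 2
        v_r = -2 * nir / s ** 2
        f_nn = d2g * v_n ** 2 + dg * (-4 * r / s ** 3)
        f_rr = d2g * v_r ** 2 + dg * (4 * nir / s ** 3)
        f_nr = d2g * v_n * v_r + dg * (2 * (nir - r) / s ** 3)
        return f_nn, f_rr, f_nr


def fit_semiempirical_g(lut: LUTTable, degree: int = 3) -> SemiEmpiricalLAIFn:
    """Least-squares polynomial fit of LAI against the LUT's NDVI feature.

    A cubic is the default: the lowest order with non-trivial curvature
    (the Taylor factor needs second derivatives) that stays twice
    differentiable everywhere."""
    ndvi = lut.feature_column("NDVI")
    lai = lut.lai
    distinct = np.unique(ndvi).size
    if lut.n < 10 or distinct < 10:
        raise ValueError("need >= 10 LUT entries with distinct NDVI")
    if distinct <= degree:
        raise ValueError("rank-deficient design: too few distinct NDVI values")
    coeffs = np.polynomial.polynomial.polyfit(ndvi, lai, degree)
    resid = lai - np.polynomial.polynomial.polyval(ndvi, coeffs)
    return SemiEmpiricalLAIFn(coeffs,
                              ndvi_domain=(float(ndvi.min()), float(ndvi.max())),
                              fit_rmse=float(np.sqrt(np.mean(resid ** 2))))


@dataclass
class QuadraticFn:
    """Test function f = a N^2 + b R^2 + c N R + d N + e R + f0 with exact
    analytic Hessian; the Taylor factor is exact for it."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    f0: float = 0.0

    def __call__(self, nir, r):
        return self.f(nir, r)

    def f(self, nir, r):
        nir, r = np.asarray(nir, dtype=float), np.asarray(r, dtype=float)
        return (self.a * nir ** 2 + self.b * r ** 2 + self.c * nir * r
                + self.d * nir + self.e * r + self.f0)

    def hessian(self, nir, r):
        shape = np.broadcast(np.asarray(nir), np.asarray(r)).shape
        return (np.full(shape, 2 * self.a), np.full(shape, 2 * self.b),
                np.full(shape, self.c))


class NumericalBivariateFn:
    """Wrap any callable f(NIR, R) with central-finite-difference second
    partials, for Taylor-correcting functions without analytic Hessians
    (e.g. the VI formulas themselves)."""

    def __init__(self, fn, h: float = 1e-4):
        self.fn = fn
        self.h = h

    def __call__(self, nir, r):
        return self.fn(nir, r)

    def f(self, nir, r):
        return self.fn(nir, r)

    def hessian(self, nir, r):
        fn, h = self.fn, self.h
        nir, r = np.asarray(nir, dtype=float), np.asarray(r, dtype=float)
        f0 = fn(nir, r)
        f_nn = (fn(nir + h, r) - 2 * f0 + fn(nir - h, r)) / h ** 2
        f_rr = (fn(nir, r + h) - 2 * f0 + fn(nir, r - h)) / h ** 2
        f_nr = (fn(nir + h, r + h) - fn(nir + h, r - h)
                - fn(nir - h, r + h) + fn(nir - h, r - h)) / (4 * h ** 2)
        return f_nn, f_rr, f_nr


# ---------------------------------------------------------------------------
# windowed moments
# ---------------------------------------------------------------------------

@dataclass
class WindowMoments:
    """Per-coarse-pixel first/second moments of the fine NIR and red bands
    (population normalization)."""

    nir_mean: np.ndarray
    r_mean: np.ndarray
    var_nir: np.ndarray
    var_r: np.ndarray
    cov: np.ndarray
    n: np.ndarray
    method: str = "footprint"

    def __post_init__(self):
        if np.any(self.var_nir[np.isfinite(self.var_nir)] < -1e-12):
            raise ValueError("negative variance")


def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = a.shape
    return a.reshape(nr // factor, factor, nc // factor, factor).transpose(0, 2, 1, 3)


def windowed_moments(nir: np.ndarray, red: np.ndarray, factor: int | None = None,
                     window: int = 40, valid=None) -> WindowMoments:
    """Moments per coarse pixel.

    With ``factor`` given, each coarse pixel's moments come from the exact
    factor x factor fine-pixel footprint (synchronized fine coverage).
    Without it, a sliding ``window`` x ``window`` fine-pixel box centred on
    each pixel is the fallback (method tag "fallback-window"); the default
    40 matches a 4 m coarse pixel over 0.1 m fine pixels."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise ValueError("NIR and red rasters are not aligned")
    if factor is not None:
        nr, nc = nir.shape
        if nr % factor or nc % factor:
            raise ValueError("raster shape not divisible by the aggregation factor")
        bn = _block_view(nir, factor).reshape(nr // factor, nc // factor, -1)
        br = _block_view(red, factor).reshape(nr // factor, nc // factor, -1)
        if valid is not None:
            v = _block_view(np.asarray(valid, bool), factor).reshape(nr // factor, nc // factor, -1)
            bn = np.where(v, bn, np.nan)
            br = np.where(v, br, np.nan)
            n = v.sum(axis=2)
            if np.any(n == 0):
                log.warning("windowed_moments: %d footprints with zero valid fine pixels "
                            "flagged NaN", int((n == 0).sum()))
        else:
            n = np.full(bn.shape[:2], factor * factor)
        import warnings as _warnings
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN footprints
            nm = np.nanmean(bn, axis=2)
            rm = np.nanmean(br, axis=2)
            vn = np.nanmean(bn ** 2, axis=2) - nm ** 2
            vr = np.nanmean(br ** 2, axis=2) - rm ** 2
            cv = np.nanmean(bn * br, axis=2) - nm * rm
        return WindowMoments(nm, rm, np.maximum(vn, 0.0), np.maximum(vr, 0.0), cv, n,
                             method="footprint")
    # sliding-window fallback on the raster's own grid
    size = window
    mean = lambda a: ndimage.uniform_filter(a, size=size, mode="nearest")
    nm, rm = mean(nir), mean(red)
    vn = mean(nir ** 2) - nm ** 2
    vr = mean(red ** 2) - rm ** 2
    cv = mean(nir * red) - nm * rm
    n = np.full(nir.shape, size * size)
    return WindowMoments(nm, rm, np.maximum(vn, 0.0), np.maximum(vr, 0.0), cv, n,
                         method="fallback-window")


# ---------------------------------------------------------------------------
# spatial effect factor k
# ---------------------------------------------------------------------------

@dataclass
class ScaleFactorMap:
    """Per-coarse-pixel Taylor scale-effect factor k (LAI units)."""

    k: np.ndarray
    method: str = "footprint"
    provenance: dict = field(default_factory=dict)


def compute_k(moments: WindowMoments, fn) -> ScaleFactorMap:
    """Second-order Taylor scale factor per coarse pixel,

        k = -1/2 [f_NN VAR_NIR + f_RR VAR_R + 2 f_NR COV],

    with the second partials of ``fn`` evaluated at the footprint means.
    ``fn`` needs only a ``hessian(nir, r)`` method.  Homogeneous footprints
    give k = 0 exactly; footprints with NIR_m + R_m = 0 are flagged NaN."""
    nm, rm = moments.nir_mean, moments.r_mean
    undefined = ~np.isfinite(nm) | ~np.isfinite(rm) | (nm + rm <= 0)
    n_und = int(undefined.sum())
    if n_und:
        log.warning("compute_k: %d pixels with undefined means flagged NaN", n_und)
    nm_safe = np.where(undefined, 1.0, nm)
    rm_safe = np.where(undefined, 1.0, rm)
    f_nn, f_rr, f_nr = fn.hessian(nm_safe, rm_safe)
    k = -0.5 * (f_nn * moments.var_nir + f_rr * moments.var_r + 2 * f_nr * moments.cov)
    k = np.where(undefined, np.nan, k)
    prov = {"method": moments.method, "fn": type(fn).__name__}
    if hasattr(fn, "coeffs"):
        prov["g_coeffs"] = list(np.asarray(fn.coeffs, dtype=float))
    return ScaleFactorMap(np.asarray(k, dtype=float), moments.method, prov)


def exact_scale_bias(fine_nir: np.ndarray, fine_red: np.ndarray, factor: int, fn) -> np.ndarray:
    """Brute-force oracle k_exact = f(mean) - mean(f) per coarse footprint."""
    nr, nc = fine_nir.shape
    bn = _block_view(np.asarray(fine_nir, float), factor).reshape(nr // factor, nc // factor, -1)
    br = _block_view(np.asarray(fine_red, float), factor).reshape(nr // factor, nc // factor, -1)
    return fn.f(bn.mean(axis=2), br.mean(axis=2)) - fn.f(bn, br).mean(axis=2)


# ---------------------------------------------------------------------------
# scale-corrected inversion
# ---------------------------------------------------------------------------

@dataclass
class ScaledInversionConfig:
    """Weights of the modified cost function.

    ``band_error`` is the per-band observation error eps_b; if None it
    defaults per pixel to (rel_band_error * rho_obs)^2 + band_error_floor,
    following the few-percent reflectance uncertainty of calibrated
    imagery.  ``eps_lai`` is the squared prior width (default (0.5)^2
    (m2/m2)^2); infinity disables the prior term."""

    band_error: np.ndarray | None = None
    rel_band_error: float = 0.02
    band_error_floor: float = 1e-6
    eps_lai: float = 0.25
    lai_expectation: float | np.ndarray = 0.0
    q: int = 1

    def __post_init__(self):
        if self.eps_lai <= 0:
            raise ValueError("eps_lai must be > 0")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.band_error is not None:
            be = np.asarray(self.band_error, dtype=float)
            if np.any(be <= 0):
                raise ValueError("band errors must be > 0")
            self.band_error = be


def invert_lai_scaled(band_obs: np.ndarray, lut: LUTTable, k,
                      config: ScaledInversionConfig,
                      band_feature_indices=None):
    """Minimize the k-modified cost per pixel over LUT entries.

    ``band_obs``: (n_pixels, n_bands) observed band reflectances (the
    spectral term compares these against the LUT's band features);
    ``band_feature_indices`` selects which LUT feature columns are bands
    (default: the first n_bands columns).  ``k``: per-pixel scale factor
    (missing/NaN values fall back to 0 with a logged count).  Returns the
    minimizing entry's LAI (mean of q best)."""
    obs = np.atleast_2d(np.asarray(band_obs, dtype=float))
    n_pix, n_bands = obs.shape
    if band_feature_indices is None:
        band_feature_indices = np.arange(n_bands)
    sim = lut.features[:, band_feature_indices]  # (n_lut, n_bands)
    if sim.shape[1] != n_bands:
        raise ValueError("observation bands do not match the LUT band features")
    k_arr = np.broadcast_to(np.asarray(k, dtype=float), (n_pix,)).copy()
    n_missing = int(np.sum(~np.isfinite(k_arr)))
    if n_missing:
        log.warning("invert_lai_scaled: %d pixels missing k, falling back to k=0", n_missing)
        k_arr[~np.isfinite(k_arr)] = 0.0
    lai_e = np.broadcast_to(np.asarray(config.lai_expectation, dtype=float), (n_pix,))
    out = np.full(n_pix, np.nan)
    finite = np.all(np.isfinite(obs), axis=1)
    idx_finite = np.nonzero(finite)[0]
    q = min(config.q, lut.n)
    chunk = _chunk_size(lut.n, n_bands)
    for start in range(0, idx_finite.size, chunk):
        sel = idx_finite[start:start + chunk]
        o = obs[sel]
        if config.band_error is not None:
            eps = np.broadcast_to(config.band_error, o.shape)
        else:
            eps = (config.rel_band_error * o) ** 2 + config.band_error_floor
        with np.errstate(over="ignore"):
            spectral = np.mean((o[:, None, :] - sim[None, :, :]) ** 2 / eps[:, None, :], axis=2)
            if np.isfinite(config.eps_lai):
                prior = ((lut.lai[None, :] - k_arr[sel, None] - lai_e[sel, None]) ** 2
                         / config.eps_lai)
                cost = spectral + prior
            else:
                cost = spectral
        if q == 1:
            out[sel] = lut.lai[np.argmin(cost, axis=1)]
        else:
            part = np.argpartition(cost, q - 1, axis=1)[:, :q]
            for row, pix in enumerate(sel):
                cand = part[row]
                cand = cand[np.lexsort((cand, cost[row, cand]))]
                out[pix] = lut.lai[cand].mean()
    return out


def retrieve_lai_corrected(band_images: np.ndarray, lut: LUTTable,
                           k_map: ScaleFactorMap, feature_extractor,
                           config: ScaledInversionConfig | None = None):
    """Full scale-corrected satellite LAI retrieval on a coarse image.

    ``band_images``: (n_bands, rows, cols) sensor band reflectances.
    Steps: (1) plain LUT inversion per pixel; (2) the prior expectation
    LAI_e = 3x3-median of (plain - k), a truth-scale field; (3) modified
    cost function inversion; (4) subtract k to express the result on the
    true (fine-mean LAI) scale.  Returns (corrected map, plain map)."""
    config = config or ScaledInversionConfig()
    nb, nr, nc = band_images.shape
    bands_flat = band_images.reshape(nb, -1).T  # (n_pix, n_bands)
    feats = feature_extractor.from_bands(bands_flat)
    plain = invert_lai_lut(feats, lut, q=config.q).reshape(nr, nc)
    k = k_map.k
    k_filled = np.where(np.isfinite(k), k, 0.0)
    lai_e = ndimage.median_filter(plain - k_filled, size=3, mode="nearest")
    cfg = ScaledInversionConfig(
        band_error=config.band_error, rel_band_error=config.rel_band_error,
        band_error_floor=config.band_error_floor, eps_lai=config.eps_lai,
        lai_expectation=lai_e.ravel(), q=config.q)
    scaled = invert_lai_scaled(bands_flat, lut, k_filled.ravel(), cfg,
                               band_feature_indices=np.arange(nb))
    corrected = scaled.reshape(nr, nc) - k_filled
    return corrected, plain
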