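"""End-to-end multi-scale biomass mapping workflow.

The synergy strategy: (1) estimate AGB at the fine (UAV) scale from
optimized vegetation indices plus LUT-retrieved LAI, trained on the
ground plots; (2) block-aggregate the fine AGB map to the satellite grid
to build a dense coarse training sample set; (3) retrieve satellite LAI
with the Taylor scale-effect correction; (4) train the satellite AGB
model (random forest on five wideband VIs + LAI) on the aggregated
samples and map the whole scene; (5) quantify the residual scale bias and
treatment effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geo_io import Raster, make_provenance, write_raster
from .canopy_rt import (SpectralGrid, SensorSRF, gf2_srf, convolve_srf, draw_lut_spectra,
                        LUTTable, HyperspectralFeatures, SensorBandFeatures,
                        DEFAULT_LUT_RANGES)
from .spectral_indices import (VI_NAMES, VIDefinition, vi_formula, optimize_band_pair,
                               select_sensitive_bands, plot_footprint_means)
from .lai_retrieval import (invert_lai_lut, fit_semiempirical_g, windowed_moments,
                            compute_k, ScaledInversionConfig, retrieve_lai_corrected,
                            NumericalBivariateFn)
from .agb_regression import (FeatureTable, ModelSpec, split_samples, fit_model,
                             evaluate, ValidationReport)
from .synthetic_scene import SyntheticScene

__all__ = [
    "AggregationSpec",
    "aggregate_map",
    "build_sample_set",
    "ScaleBiasReport",
    "scale_bias_analysis",
    "TreatmentSummary",
    "treatment_summary",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "directional_battery",
    "SATELLITE_VI_NAMES",
]

log = logging.getLogger("grassagb")

#: wideband indices computable from the 4-band multispectral sensor
SATELLITE_VI_NAMES = ("RVI", "NDVI", "RDVI", "OSAVI", "MSAVI")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregationSpec:
    """Block aggregation: integer factor per axis, minimum valid fine-pixel
    fraction for a coarse pixel to be valid (default 1.0: fully valid
    blocks only), alignment at the raster origin."""

    factor: int
    min_valid_fraction: float = 1.0

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if not (0 < self.min_valid_fraction <= 1):
            raise ValueError("valid fraction must be in (0, 1]")


def aggregate_map(fine, spec: AggregationSpec):
    """Block mean over valid fine pixels.  NaN (or meta nodata) fine pixels
    are invalid; a coarse pixel falls below the valid-fraction threshold
    becomes NaN.  Edge blocks beyond the divisible extent are dropped with
    a log message.  Accepts a 2-D array or Raster; returns the same kind."""
    raster = fine if isinstance(fine, Raster) else None
    a = np.asarray(fine.data if raster is not None else fine, dtype=float)
    if a.ndim != 2:
        raise ValueError("aggregate_map needs a single-band raster")
    f = spec.factor
    nr, nc = a.shape
    if f > nr or f > nc:
        raise ValueError("aggregation factor larger than the raster")
    if nr % f or nc % f:
        log.warning("aggregate_map: dropping %d edge rows and %d edge cols",
                    nr % f, nc % f)
        a = a[:nr - nr % f, :nc - nc % f]
        nr, nc = a.shape
    if raster is not None and np.isfinite(raster.meta.nodata):
        a = np.where(a == raster.meta.nodata, np.nan, a)
    blocks = a.reshape(nr // f, f, nc // f, f).transpose(0, 2, 1, 3).reshape(nr // f, nc // f, -1)
    valid = np.isfinite(blocks)
    n_valid = valid.sum(axis=2)
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.where(valid, blocks, 0.0), axis=2) / np.maximum(n_valid, 1)
    means = np.where(n_valid / (f * f) >= spec.min_valid_fraction - 1e-12, means, np.nan)
    means = np.where(n_valid == 0, np.nan, means)
    if raster is None:
        return means
    return Raster(means, raster.meta.coarsened(f), raster.provenance)


# ---------------------------------------------------------------------------
# sample sets
# ---------------------------------------------------------------------------

def build_sample_set(coarse_agb, feature_rasters: dict, mask=None,
                     scale: str = "aggregated-coarse"):
    """One training sample per coarse pixel passing every mask.

    Exclusion causes are counted per class ('null' = non-finite AGB,
    'invalid_feature', 'negative', 'masked').  Returns (FeatureTable,
    exclusion dict)."""
    agb = np.asarray(coarse_agb.data if isinstance(coarse_agb, Raster) else coarse_agb,
                     dtype=float)
    feats = {k: np.asarray(v.data if isinstance(v, Raster) else v, dtype=float)
             for k, v in feature_rasters.items()}
    for k, v in feats.items():
        if v.shape != agb.shape:
            raise ValueError(f"feature raster {k!r} not co-registered with the AGB map")
    null = ~np.isfinite(agb)
    invalid_feature = np.zeros_like(null)
    for v in feats.values():
        invalid_feature |= ~np.isfinite(v)
    negative = np.isfinite(agb) & (agb < 0)
    masked = np.zeros_like(null) if mask is None else ~np.asarray(mask, bool)
    keep = ~(null | invalid_feature | negative | masked)
    excluded = {
        "null": int(null.sum()),
        "invalid_feature": int((invalid_feature & ~null).sum()),
        "negative": int((negative & ~null & ~invalid_feature).sum()),
        "masked": int((masked & ~null & ~invalid_feature & ~negative).sum()),
    }
    if not keep.any():
        raise ValueError(f"empty sample set; exclusions: {excluded}")
    rows, cols = np.nonzero(keep)
    X = pd.DataFrame({k: v[keep] for k, v in feats.items()})
    ids = np.array([f"r{r}c{c}" for r, c in zip(rows, cols)])
    table = FeatureTable(X, agb[keep], ids, scale=scale)
    if any(excluded.values()):
        log.info("build_sample_set: %d samples, exclusions %s", table.n, excluded)
    return table, excluded


# ---------------------------------------------------------------------------
# scale bias
# ---------------------------------------------------------------------------

@dataclass
class ScaleBiasReport:
    """Per-coarse-pixel absolute relative error of an estimated AGB map
    against the aggregated fine-scale reference (percent)."""

    relative_errors_pct: np.ndarray
    mean_pct: float
    max_pct: float
    hist_bin_edges: np.ndarray
    hist_counts: np.ndarray
    n: int
    n_excluded_nonpositive_ref: int = 0


def scale_bias_analysis(estimated, reference, n_bins: int = 20) -> ScaleBiasReport:
    """Relative error 100*|est - ref|/ref per coarse pixel where both maps
    are valid and ref > 0."""
    if isinstance(estimated, Raster) and isinstance(reference, Raster) \
            and estimated.meta.crs != reference.meta.crs:
        raise ValueError("CRS mismatch between estimated and reference maps "
                         "(no reprojection is performed)")
    est = np.asarray(estimated.data if isinstance(estimated, Raster) else estimated, float)
    ref = np.asarray(reference.data if isinstance(reference, Raster) else reference, float)
    if est.shape != ref.shape:
        raise ValueError("maps are not co-registered")
    both = np.isfinite(est) & np.isfinite(ref)
    if not both.any():
        raise ValueError("estimated and reference maps have disjoint valid footprints")
    nonpos = both & (ref <= 0)
    use = both & (ref > 0)
    rel = 100.0 * np.abs(est[use] - ref[use]) / ref[use]
    try:
        counts, edges = np.histogram(rel, bins=n_bins)
    except ValueError:  # (near-)degenerate error range
        counts, edges = np.histogram(rel, bins=1)
    return ScaleBiasReport(rel, float(rel.mean()), float(rel.max()), edges, counts,
                           int(rel.size), int(nonpos.sum()))


# ---------------------------------------------------------------------------
# treatment summary
# ---------------------------------------------------------------------------

@dataclass
class TreatmentSummary:
    """Per-treatment mean AGB and percent change against the control;
    also the grouped April-fertilization change
    100*(mean(avg(I4), avg(O4)) - avg(CK))/avg(CK)."""

    means_g_m2: dict
    counts: dict
    control: str
    pct_change_vs_control: dict
    april_group_change_pct: float = float("nan")
    empty_treatments: tuple = ()


def treatment_summary(agb_map, treatment_map, labels, control: str = "CK") -> TreatmentSummary:
    """Masked per-treatment means over an AGB map.

    ``treatment_map`` holds integer indices into ``labels`` (or can be an
    array of label strings)."""
    agb = np.asarray(agb_map.data if isinstance(agb_map, Raster) else agb_map, float)
    treat = np.asarray(treatment_map.data if isinstance(treatment_map, Raster)
                       else treatment_map)
    if treat.shape != agb.shape:
        raise ValueError("treatment raster does not cover the AGB map")
    if control not in labels:
        raise ValueError(f"control {control!r} not among labels {labels}")
    means, counts, empty = {}, {}, []
    for idx, label in enumerate(labels):
        m = (treat == label) if treat.dtype.kind in "SU" else (treat == idx)
        m = m & np.isfinite(agb)
        counts[label] = int(m.sum())
        if counts[label] == 0:
            empty.append(label)
            means[label] = float("nan")
            log.warning("treatment_summary: treatment %s is empty", label)
        else:
            means[label] = float(agb[m].mean())
    ck = means[control]
    pct = {lab: (100.0 * (means[lab] - ck) / ck if np.isfinite(means[lab]) and lab not in empty
                 else float("nan"))
           for lab in labels}
    april = float("nan")
    if all(lab in means and np.isfinite(means.get(lab, np.nan)) for lab in ("I4", "O4")) \
            and np.isfinite(ck) and ck > 0:
        april = 100.0 * ((means["I4"] + means["O4"]) / 2.0 - ck) / ck
    return TreatmentSummary(means, counts, control, pct, april, tuple(empty))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Stage parameters of the end-to-end run (desk-scale defaults; see
    docs/methods.md for the sizing rationale).

    Model comparisons (VIs vs VIs+LAI; aggregated vs plot-only samples) use
    a repeated-holdout protocol: ``n_split_repeats`` seeded 60/20/20
    partitions x ``n_rf_repeats`` forest seeds, reporting the mean
    validation R^2 per arm.  Vegetation-index band pairs are re-optimized
    on each partition's *training* plots only, so no selection information
    leaks into validation."""

    lut_n: int = 2000
    lut_ranges: dict = field(default_factory=lambda: dict(DEFAULT_LUT_RANGES))
    n_sensitive_bands: int = 5
    vi_pairs: dict | None = None      # {vi_name: (wl_i, wl_j)}; None = exhaustive search
    rf_trees: int = 500
    split_fractions: tuple = (0.6, 0.2, 0.2)
    n_split_repeats: int = 10
    n_rf_repeats: int = 1
    eps_lai: float = 0.25             # squared prior width, (m2/m2)^2
    rel_band_error: float = 0.02
    q: int = 30                       # LUT candidates averaged per retrieval
    correct_vi_scale: bool = False    # Taylor-correct the satellite VIs too
    seed: int = 0


@dataclass
class PipelineResult:
    uav_lai_map: Raster
    uav_agb_map: Raster
    aggregated_agb: Raster
    k_map: np.ndarray
    satellite_lai_plain: Raster
    satellite_lai_corrected: Raster
    satellite_agb_map: Raster
    satellite_agb_map_uncorrected: Raster
    vi_definitions: dict
    comparison: dict                  # repeated-holdout mean validation R^2 per arm
    uav_report_vis: ValidationReport
    uav_report_vis_lai: ValidationReport
    sat_report_aggregated: ValidationReport
    sat_report_plot_only: ValidationReport
    bias_corrected: ScaleBiasReport
    bias_uncorrected: ScaleBiasReport
    treatments: TreatmentSummary
    sample_count: int
    exclusions: dict
    g_fit_rmse: float
    lai_error_corrected: float = float("nan")  # vs aggregated fine truth, if known
    lai_error_plain: float = float("nan")

    def summary(self) -> dict:
        return {
            "uav_r2_vis": self.comparison["uav_r2_vis"],
            "uav_r2_vis_lai": self.comparison["uav_r2_vis_lai"],
            "uav_rmse_vis": self.uav_report_vis.rmse_g_m2,
            "uav_rmse_vis_lai": self.uav_report_vis_lai.rmse_g_m2,
            "sat_r2_aggregated": self.comparison["sat_r2_aggregated"],
            "sat_r2_plot_only": self.comparison["sat_r2_plot_only"],
            "mean_bias_corrected_pct": self.bias_corrected.mean_pct,
            "mean_bias_uncorrected_pct": self.bias_uncorrected.mean_pct,
            "n_samples": self.sample_count,
            "april_group_change_pct": self.treatments.april_group_change_pct,
        }


def _vi_table(cube_spectra: np.ndarray, wavelengths: np.ndarray, vi_defs: dict) -> pd.DataFrame:
    """Evaluate VI definitions on (n, n_wl) spectra."""
    cols = {}
    for name, (wi, wj) in vi_defs.items():
        i = int(np.argmin(np.abs(wavelengths - wi)))
        j = int(np.argmin(np.abs(wavelengths - wj)))
        cols[name] = vi_formula(name)(cube_spectra[:, i], cube_spectra[:, j])
    return pd.DataFrame(cols)


def _sat_vi_frame(bands: np.ndarray, srf: SensorSRF, k_vi=None) -> pd.DataFrame:
    """Wideband VIs from (n_pix, 4) sensor bands (i = red, j = NIR); if
    ``k_vi`` maps names to per-pixel Taylor factors, subtract them."""
    red = bands[:, srf.band_index("red")]
    nir = bands[:, srf.band_index("nir")]
    cols = {}
    for name in SATELLITE_VI_NAMES:
        v = vi_formula(name)(red, nir)
        if k_vi is not None and name in k_vi:
            v = v - k_vi[name]
        cols[name] = v
    return pd.DataFrame(cols)


def _split_indices(n: int, fractions, seed: int):
    """Train/test/validation index arrays: the same seeded largest-remainder
    partition :func:`grassagb.agb_regression.split_samples` produces."""
    from .agb_regression import largest_remainder_sizes
    sizes = largest_remainder_sizes(n, fractions)
    perm = np.random.default_rng(seed).permutation(n)
    parts, start = [], 0
    for s in sizes:
        parts.append(np.sort(perm[start:start + s]))
        start += s
    return parts


def run_pipeline(scene: SyntheticScene, config: PipelineConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Execute the full ground-UAV-satellite workflow on a scene."""
    config = config or PipelineConfig()
    rng_seq = np.random.SeedSequence(config.seed)
    children = rng_seq.spawn(3)
    lut_seed = int(children[0].generate_state(1)[0] % (2 ** 31))
    split_seeds = [int(s % (2 ** 31)) for s in
                   children[1].generate_state(config.n_split_repeats)]
    rf_seeds = [int(s % (2 ** 31)) for s in
                children[2].generate_state(config.n_rf_repeats)]
    grid = scene.grid
    wl = grid.wavelengths_nm
    cube = scene.uav_cube.data
    nb, nr, nc = cube.shape
    plots = scene.plots
    n_plots = len(plots)
    plot_ids = np.array([p.plot_id for p in plots])
    plot_agb = np.array([p.agb_g_m2 for p in plots])
    f = scene.config.factor
    rf_spec = lambda seed: ModelSpec("RF", hyperparams={"n_trees": config.rf_trees},
                                     seed=seed)

    # --- stage 1: UAV LUT, sensitive bands, fine LAI map ---
    draws, lut_spectra = draw_lut_spectra(config.lut_n, config.lut_ranges, grid, lut_seed,
                                          g=scene.config.g,
                                          sun_zenith_deg=scene.config.sun_zenith_deg)
    sensitive = select_sensitive_bands(lut_spectra, draws["lai"],
                                       config.n_sensitive_bands, wavelengths_nm=wl)
    uav_features = HyperspectralFeatures(grid, tuple(sensitive))
    uav_lut = LUTTable(draws["lai"], draws, uav_features.from_spectra(lut_spectra),
                       tuple(uav_features.names),
                       make_provenance({"n": config.lut_n}, seed=lut_seed))
    pix_spectra = cube.reshape(nb, -1).T.astype(float)
    uav_lai = invert_lai_lut(uav_features.from_spectra(pix_spectra), uav_lut,
                             q=config.q).reshape(nr, nc)
    plot_spectra = plot_footprint_means(scene.uav_cube, plots)
    plot_lai_est = invert_lai_lut(uav_features.from_spectra(plot_spectra), uav_lut,
                                  q=config.q)
    log.info("stage uav-lai done (sensitive bands %s)", sensitive)

    # --- stage 2: UAV AGB — repeated-holdout VIs vs VIs+LAI comparison;
    # band pairs are optimized on each partition's training plots only ---
    r2_vis_acc, r2_lai_acc = [], []
    vi_defs_final = None
    final_parts = None
    vis_final = None
    for si, s_seed in enumerate(split_seeds):
        tr, te, va = _split_indices(n_plots, config.split_fractions, s_seed)
        if config.vi_pairs is None:
            train_plots = [plots[i] for i in tr]
            vi_defs_s = {name: optimize_band_pair(scene.uav_cube, train_plots,
                                                  name).best_pair
                         for name in VI_NAMES}
        else:
            vi_defs_s = dict(config.vi_pairs)
        vis_s = _vi_table(plot_spectra, wl, vi_defs_s)
        both = (vis_s, vis_s.assign(LAI=plot_lai_est))
        for rf_seed in rf_seeds:
            for X, acc in zip(both, (r2_vis_acc, r2_lai_acc)):
                tbl = FeatureTable(X, plot_agb, plot_ids)
                model = fit_model(rf_spec(rf_seed), tbl.subset(tr))
                acc.append(evaluate(model, tbl.subset(va)).r2)
        if si == 0:
            vi_defs_final, final_parts, vis_final = vi_defs_s, (tr, te, va), vis_s
    comparison = {"uav_r2_vis": float(np.mean(r2_vis_acc)),
                  "uav_r2_vis_lai": float(np.mean(r2_lai_acc))}

    # final-split reports and the fine AGB map (mean over forest seeds)
    tr0, _, va0 = final_parts
    tbl_vis = FeatureTable(vis_final, plot_agb, plot_ids)
    tbl_lai = FeatureTable(vis_final.assign(LAI=plot_lai_est), plot_agb, plot_ids)
    uav_report_vis = evaluate(fit_model(rf_spec(rf_seeds[0]), tbl_vis.subset(tr0)),
                              tbl_vis.subset(va0), split="validation")
    map_models = [fit_model(rf_spec(s), tbl_lai.subset(tr0)) for s in rf_seeds]
    uav_report_lai = evaluate(map_models[0], tbl_lai.subset(va0), split="validation")
    fine_X = _vi_table(pix_spectra, wl, vi_defs_final).assign(LAI=uav_lai.ravel())
    uav_agb = np.mean([m.predict(fine_X) for m in map_models], axis=0).reshape(nr, nc)
    log.info("stage uav-agb done (repeated R2 %.3f vs %.3f)",
             comparison["uav_r2_vis"], comparison["uav_r2_vis_lai"])

    # --- stage 3: aggregation to the satellite grid ---
    agg_agb = aggregate_map(Raster(uav_agb, scene.agb.meta), AggregationSpec(factor=f))

    # --- stage 4: satellite LUT, scale factor k, corrected LAI ---
    srf = scene.srf
    sat_features = SensorBandFeatures(srf)
    sat_lut = LUTTable(draws["lai"], draws, sat_features.from_spectra(lut_spectra),
                       tuple(sat_features.names),
                       make_provenance({"n": config.lut_n, "srf": srf.band_names},
                                       seed=lut_seed))
    g_fn = fit_semiempirical_g(sat_lut)
    fine_bands = convolve_srf(cube.astype(float), srf)  # (4, nr, nc)
    moments = windowed_moments(fine_bands[srf.band_index("nir")],
                               fine_bands[srf.band_index("red")], factor=f)
    k_map = compute_k(moments, g_fn)
    inv_cfg = ScaledInversionConfig(rel_band_error=config.rel_band_error,
                                    eps_lai=config.eps_lai, q=config.q)
    sat_bands = scene.satellite.data.astype(float)
    sat_lai_corr, sat_lai_plain = retrieve_lai_corrected(sat_bands, sat_lut, k_map,
                                                         sat_features, inv_cfg)
    truth_lai_coarse = aggregate_map(scene.lai.data, AggregationSpec(factor=f))
    lai_err_corr = float(np.nanmean(np.abs(sat_lai_corr - truth_lai_coarse)))
    lai_err_plain = float(np.nanmean(np.abs(sat_lai_plain - truth_lai_coarse)))
    log.info("stage satellite-lai done (g RMSE %.3f; LAI err %.3f corrected, "
             "%.3f plain)", g_fn.fit_rmse, lai_err_corr, lai_err_plain)

    # --- stage 5: satellite feature rasters and sample sets ---
    nrc, ncc = agg_agb.data.shape
    sat_pix = sat_bands.reshape(len(srf.band_names), -1).T
    k_vi = None
    if config.correct_vi_scale:
        k_vi = {}
        red_f, nir_f = fine_bands[srf.band_index("red")], fine_bands[srf.band_index("nir")]
        for name in SATELLITE_VI_NAMES:
            fn = NumericalBivariateFn(
                lambda n_, r_, _f=vi_formula(name): _f(r_, n_))  # f(NIR, R) ordering
            k_vi[name] = compute_k(windowed_moments(nir_f, red_f, factor=f), fn).k.ravel()
    sat_vis = _sat_vi_frame(sat_pix, srf, k_vi)
    feat_names = list(SATELLITE_VI_NAMES) + ["LAI"]
    feats_corr = {n: sat_vis[n].to_numpy().reshape(nrc, ncc) for n in SATELLITE_VI_NAMES}
    feats_corr["LAI"] = sat_lai_corr
    feats_unc = dict(feats_corr)
    feats_unc["LAI"] = sat_lai_plain
    table_corr, excl = build_sample_set(agg_agb, feats_corr)
    table_unc, _ = build_sample_set(agg_agb, feats_unc)

    # coarse features at each plot's coarse pixel (for the plot-only model)
    meta_c = agg_agb.meta
    pc, pr = meta_c.xy_to_colrow(np.array([p.x for p in plots]),
                                 np.array([p.y for p in plots]))
    pr = np.clip(np.rint(pr).astype(int), 0, nrc - 1)
    pc = np.clip(np.rint(pc).astype(int), 0, ncc - 1)
    plot_sat_tbl = FeatureTable(
        pd.DataFrame({n: feats_corr[n][pr, pc] for n in feat_names}),
        plot_agb, plot_ids, scale="plot")

    # --- stage 6: satellite AGB — repeated aggregated vs plot-only
    # comparison (both judged against held-out ground plots) ---
    r2_agg_acc, r2_plot_acc = [], []
    for s_seed in split_seeds:
        tr_p, _, va_p = _split_indices(n_plots, config.split_fractions, s_seed)
        tr_a, _, _ = _split_indices(table_corr.n, config.split_fractions, s_seed)
        for rf_seed in rf_seeds:
            model_agg = fit_model(rf_spec(rf_seed), table_corr.subset(tr_a))
            model_plot = fit_model(rf_spec(rf_seed), plot_sat_tbl.subset(tr_p))
            va_tbl = plot_sat_tbl.subset(va_p)
            r2_agg_acc.append(evaluate(model_agg, va_tbl).r2)
            r2_plot_acc.append(evaluate(model_plot, va_tbl).r2)
    comparison["sat_r2_aggregated"] = float(np.mean(r2_agg_acc))
    comparison["sat_r2_plot_only"] = float(np.mean(r2_plot_acc))

    tr_p0, _, va_p0 = _split_indices(n_plots, config.split_fractions, split_seeds[0])
    tr_a0, _, _ = _split_indices(table_corr.n, config.split_fractions, split_seeds[0])
    sat_models_corr = [fit_model(rf_spec(s), table_corr.subset(tr_a0)) for s in rf_seeds]
    sat_models_unc = [fit_model(rf_spec(s), table_unc.subset(tr_a0)) for s in rf_seeds]
    va_plot_tbl = plot_sat_tbl.subset(va_p0)
    sat_report_aggregated = evaluate(sat_models_corr[0], va_plot_tbl, split="validation")
    sat_report_plot_only = evaluate(fit_model(rf_spec(rf_seeds[0]),
                                              plot_sat_tbl.subset(tr_p0)),
                                    va_plot_tbl, split="validation")

    X_corr = pd.DataFrame({n: feats_corr[n].ravel() for n in feat_names})
    X_unc = pd.DataFrame({n: feats_unc[n].ravel() for n in feat_names})
    sat_agb_corr = np.mean([m.predict(X_corr) for m in sat_models_corr],
                           axis=0).reshape(nrc, ncc)
    sat_agb_unc = np.mean([m.predict(X_unc) for m in sat_models_unc],
                          axis=0).reshape(nrc, ncc)
    log.info("stage satellite-agb done")

    # --- stage 7: reports ---
    bias_corr = scale_bias_analysis(sat_agb_corr, agg_agb.data)
    bias_unc = scale_bias_analysis(sat_agb_unc, agg_agb.data)
    treat_coarse = aggregate_map(scene.treatment_raster.data.astype(float),
                                 AggregationSpec(factor=f))
    treatments = treatment_summary(sat_agb_corr, np.rint(treat_coarse).astype(int),
                                   scene.treatment_labels, control="CK")

    meta_c_g = replace(meta_c, units="g/m2")
    meta_c_lai = replace(meta_c, units="m2/m2")
    result = PipelineResult(
        uav_lai_map=Raster(uav_lai, replace(scene.lai.meta, units="m2/m2")),
        uav_agb_map=Raster(uav_agb, replace(scene.agb.meta, units="g/m2")),
        aggregated_agb=agg_agb,
        k_map=k_map.k,
        satellite_lai_plain=Raster(sat_lai_plain, meta_c_lai),
        satellite_lai_corrected=Raster(sat_lai_corr, meta_c_lai),
        satellite_agb_map=Raster(sat_agb_corr, meta_c_g),
        satellite_agb_map_uncorrected=Raster(sat_agb_unc, meta_c_g),
        vi_definitions=vi_defs_final,
        comparison=comparison,
        uav_report_vis=uav_report_vis,
        uav_report_vis_lai=uav_report_lai,
        sat_report_aggregated=sat_report_aggregated,
        sat_report_plot_only=sat_report_plot_only,
        bias_corrected=bias_corr,
        bias_uncorrected=bias_unc,
        treatments=treatments,
        sample_count=table_corr.n,
        exclusions=excl,
        g_fit_rmse=g_fn.fit_rmse,
        lai_error_corrected=lai_err_corr,
        lai_error_plain=lai_err_plain,
    )
    if out_dir is not None:
        _persist(result, scene, config, out_dir)
    return result


def _persist(result: PipelineResult, scene, config, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = make_provenance(asdict(config), seed=config.seed)
    write_raster(out / "uav_lai.tif", result.uav_lai_map, prov)
    write_raster(out / "uav_agb.tif", result.uav_agb_map, prov)
    write_raster(out / "aggregated_agb.tif", result.aggregated_agb, prov)
    write_raster(out / "k_map.tif",
                 Raster(result.k_map, result.satellite_lai_plain.meta), prov)
    write_raster(out / "satellite_lai.tif", result.satellite_lai_corrected, prov)
    write_raster(out / "satellite_agb.tif", result.satellite_agb_map, prov)
    report = {
        "summary": result.summary(),
        "vi_definitions": {k: list(v) for k, v in result.vi_definitions.items()},
        "exclusions": result.exclusions,
        "treatment_means_g_m2": result.treatments.means_g_m2,
        "treatment_pct_change": result.treatments.pct_change_vs_control,
        "provenance": prov,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))


def directional_battery(scene_config, pipeline_config=None, n_seeds: int = 10,
                        base_seed: int = 0):
    """Run the full pipeline on ``n_seeds`` independently seeded scenes and
    collect the three directional comparisons the synergy method predicts:
    (a) VIs+LAI >= VIs-only for the UAV model, (b) aggregated-sample
    satellite model >= plot-only model, (c) k-corrected scale bias <
    uncorrected.  Returns (per-seed records, wins dict)."""
    pipeline_config = pipeline_config or PipelineConfig()
    records = []
    for i in range(n_seeds):
        seed = base_seed + i
        sc = replace(scene_config, seed=seed)
        pc = replace(pipeline_config, seed=seed)
        from .synthetic_scene import render_scene
        res = run_pipeline(render_scene(sc), pc)
        rec = res.summary()
        rec["lai_error_corrected"] = res.lai_error_corrected
        rec["lai_error_plain"] = res.lai_error_plain
        rec["seed"] = seed
        records.append(rec)
        log.info("battery seed %d: %s", seed, {k: round(v, 3) if isinstance(v, float) else v
                                               for k, v in rec.items()})
    wins = {
        "vis_lai_ge_vis": sum(r["uav_r2_vis_lai"] >= r["uav_r2_vis"] for r in records),
        "aggregated_ge_plot": sum(r["sat_r2_aggregated"] >= r["sat_r2_plot_only"]
                                  for r in records),
        "corrected_lt_uncorrected": sum(r["mean_bias_corrected_pct"]
                                        < r["mean_bias_uncorrected_pct"] for r in records),
        "lai_corrected_lt_plain": sum(r["lai_error_corrected"] < r["lai_error_plain"]
                                      for r in records),
        "n": n_seeds,
    }
    return records, wins
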