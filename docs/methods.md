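# Methods

`grassagb` implements a ground–UAV–satellite synergy for mapping grassland
aboveground biomass (AGB, g/m²): fine-resolution imagery bridges the support
gap between 1 m² harvest plots and 4 m satellite pixels, and a second-order
Taylor expansion corrects the scale effect that nonlinear retrieval
introduces at the coarse scale. This note records the models, the choices
made where the design was open, and what the synthetic test bed does and
does not establish.

## The workflow

1. **Vegetation indices.** Six two-band indices (RVI, NDVI, RDVI, OSAVI,
   MSAVI, CI) are computed from hyperspectral reflectance. For each index,
   every ordered wavelength pair of the cube is scored by the Pearson
   correlation between the index at plot footprints and harvested AGB, and
   the best pair is kept. RDVI and MSAVI use their standard literature
   forms, `(ρj−ρi)/√(ρi+ρj)` and `(2ρj+1−√((2ρj+1)²−8(ρj−ρi)))/2`.
2. **LAI retrieval.** A look-up table (LUT) of forward-simulated canopy
   spectra is searched for the entries closest (feature RMSE) to each
   observed pixel; the retrieved LAI is the mean of the `q` best entries.
   Features are the five bands most correlated with LAI over the LUT, plus
   NDVI and OSAVI.
3. **Fine-scale AGB.** A random forest on the six optimized indices plus
   retrieved LAI, trained on the ground plots, maps AGB at the fine scale.
4. **Sample aggregation.** The fine AGB map is block-averaged to the
   satellite grid; every valid coarse pixel becomes a training sample,
   replacing the few dozen ground plots with hundreds of support-matched
   samples.
5. **Scale-effect correction.** For the semi-empirical retrieval surrogate
   `f(NIR, R) = g(NDVI)`, the bias between retrieving at the coarse pixel's
   mean signal and averaging fine-pixel retrievals is, to second order,

       k = −½ [ f_NN·VAR_NIR + f_RR·VAR_R + 2 f_NR·COV_NIR,R ],

   with the Hessian of `f` evaluated at the footprint-mean bands and the
   variances/covariance taken over the fine pixels inside the footprint
   (population normalization, which the Taylor derivation assumes). `k` is
   exact for any `f` quadratic in (NIR, R), and its truncation error decays
   superlinearly as the footprint becomes homogeneous.
6. **Corrected satellite LAI.** The coarse retrieval minimizes the modified
   cost `δ = (1/n)Σ_b (ρ_obs−ρ_sim)²/ε_b + (LAI − k − LAI_e)²/ε_LAI`.
   Because the plain coarse retrieval estimates `truth + k`, the prior
   anchors the candidate at the coarse-consistent value `LAI_e + k`, where
   `LAI_e` (the expected true footprint-mean LAI) is the 3×3-median of
   (plain retrieval − k). The final corrected product subtracts `k` to
   return to the true scale. With `ε_LAI → ∞` the scheme reduces to plain
   spectral inversion; with `ε_b → ∞` it returns the LUT entry nearest
   `LAI_e + k`.
7. **Satellite AGB.** A random forest on the five wideband indices the
   4-band sensor supports (RVI, NDVI, RDVI, OSAVI, MSAVI) plus corrected
   LAI, trained on the aggregated samples, maps AGB scene-wide; treatment
   effects are summarized per fertilization/mowing block.

## Forward model

The built-in canopy model is Beer–Lambert gap-fraction mixing:
`ρ(λ) = (1−P)·ρ_leaf(λ) + P·ρ_soil(λ)` with `P = exp(−G·LAI/cosθ_s)`,
`G = 0.5` (spherical leaf angles). It is monotone in LAI per band, which
makes LUT inversion well posed, and it is deliberately simple: the forward
model is a pluggable interface, and a full radiative-transfer code can be
substituted without touching the rest of the pipeline. The built-in leaf
and soil spectra are smooth analytic stand-ins (chlorophyll absorption,
green bump, logistic red edge onto an NIR plateau; featureless brightening
soil). LUT draws are independent uniforms; the free parameters are LAI
(0–6 m²/m²) and a soil-brightness multiplier (0.6–1.4). The leaf spectrum
is held fixed — field campaigns of this design measure leaf reflectance
directly by ground spectroscopy — while soil background genuinely varies
across a patchy degraded steppe and must be marginalized by the inversion.

The default sensor response is a set of unit-weight boxcars over the
4-band multispectral ranges 450–520, 520–590, 630–690 and 770–890 nm (the
true response curves are not published); arbitrary tabulated responses can
be loaded from CSV.

## Semi-empirical g(NDVI)

`g` is a cubic polynomial fit by least squares to the satellite LUT's
(NDVI, LAI) pairs. A cubic is the lowest-order form whose second
derivatives are non-trivial (the Taylor factor needs curvature) while
remaining twice differentiable everywhere. All partial derivatives of
`f(NIR, R) = g((NIR−R)/(NIR+R))` are analytic chain-rule expressions; a
finite-difference fallback wrapper exists for Taylor-correcting functions
without analytic Hessians (e.g. the index formulas themselves, behind the
off-by-default `correct_vi_scale` flag).

## Retrieval and cost-function parameters

- `q = 30` LUT candidates averaged per retrieval (pipeline default;
  the low-level inversion defaults to the single best entry). Averaging
  the best candidates marginalizes the soil nuisance and roughly halves
  the retrieval RMSE relative to the single best match.
- Band error `ε_b = (0.02·ρ_obs)² + 10⁻⁶`, following the few-percent
  reflectance uncertainty of calibrated imagery; prior width
  `ε_LAI = 0.25 (m²/m²)²` (i.e. ±0.5 m²/m²). Both configurable.
- Moments come from the exact coarse-pixel footprint when synchronized
  fine imagery exists; otherwise a sliding 40×40 fine-pixel-equivalent
  window is the tagged fallback (40 fine pixels = one 4 m coarse pixel at
  0.1 m resolution).
- Inversion cost ties break to the lowest LUT entry index; entries keep
  their seeded draw order.

## Regression protocol

Families: SR (univariate least squares on the single best-|r| feature),
PLSR (min(4, p−1) components), BPNN (one hidden layer of 16 units, 2000
epochs, learning rate 0.01, standardized inputs) and RF (500 trees,
unlimited depth, `mtry = p/3` per the classic regression-forest
convention). Hyperparameters are package defaults — the literature rarely
prints them — and are all configurable and seeded.

Samples split 60/20/20 into training/testing/validation by a seeded
permutation with largest-remainder rounding (ties to the earlier
fraction). Accuracy is R² — the squared Pearson correlation between
predicted and measured AGB — and RMSE in g/m².

Model *comparisons* (indices vs indices+LAI; aggregated vs plot-only
samples) use repeated holdout: the mean validation R² over 10 seeded
partitions per arm, with both arms sharing partitions and forest seeds
(paired design). A single 18-plot validation split has sampling
noise of the same order as the effects being compared; averaging
partitions measures the protocol's expected performance rather than one
draw. Band pairs are re-optimized on each partition's *training* plots
only, so no selection information leaks into validation. Final maps are
the mean prediction of the per-forest-seed models trained on the first
partition.

## Synthetic study conditions

The generator emulates a fertilization/mowing experiment on a degraded
meadow steppe:

- 0.1 m fine pixels aggregated by 40 to 4 m coarse pixels; default scene
  400×600 fine pixels (40 m × 60 m), i.e. 150 coarse pixels.
- Six treatment blocks (control CK, mowing M, organic/inorganic
  fertilization in April/July) in a 2×3 layout; LAI multipliers are the
  reference treatment-mean ratios raised to 1/β, so block AGB means
  approximate the reference means (CK 423 up to O4 622 g/m²).
- LAI: a Gaussian random field smoothed at a 1 m correlation length
  (vegetation patch scale, deliberately below the coarse pixel so the
  scale effect is active), min–max rescaled to 0.2–4.0 m²/m², amplitude
  1.0.
- Allometry `AGB = 150·LAI^1.2` with multiplicative lognormal noise,
  CV 0.25, spatially correlated at the patch scale — allometric scatter
  reflects patch-level species composition, so it must not average away
  inside a 1 m² plot the way independent per-pixel noise would.
- Soil-brightness field 0.6–1.4, correlated at the patch scale: the
  classic grassland confounder that soil-adjusted indices exist for, and
  the reason physically based LAI retrieval adds information beyond the
  indices.
- 90 plots of 1 m × 1 m, 15 per block, at least one coarse pixel apart,
  with 5% Gaussian measurement noise on plot AGB and LAI.
- Additive reflectance noise 0.005 (absolute) on the fine cube and, after
  aggregation, on the satellite image.

Scene sizes, the pipeline LUT of 2,000 entries, and the 10-scene
repetition of the directional analyses are desk-scale choices that keep a
full battery within minutes on one core; the LUT round-trip check runs at
the full 100,000-entry size. The spatial-effect factor, aggregation and
metric code are size-agnostic.

**What the synthetic bed does not show.** The forward model has no
multiple scattering, view-angle or hot-spot effects; canopy biochemistry
is frozen; atmosphere, georeferencing error and sensor PSF are absent; and
AGB depends on canopy state only through LAI. Passing the directional
tests therefore demonstrates internal consistency of the method under the
assumed generative model — heterogeneity-driven scale bias exists and the
Taylor machinery removes most of it; support-matched samples beat
mismatched ones — not field-data accuracy.

## Numerical choices and degenerate inputs

- Population (1/n) moments everywhere in the Taylor path.
- Homogeneous footprints give k = 0 exactly; footprints with
  NIR_m + R_m ≤ 0 are flagged undefined, and missing k falls back to 0
  with a logged count.
- Zero VI denominators become nodata and are counted; constant bands rank
  last in sensitive-band selection; undefined correlations are flagged,
  never silently zero.
- Aggregation requires fully valid blocks by default
  (`min_valid_fraction = 1.0`); partial blocks are configurable, edge
  remainders are dropped with a log message.
- Scale bias uses absolute relative error against the aggregated
  reference, excluding non-positive reference pixels with a count.

## Known limitations

- The cost-function prior couples the corrected retrieval to the plain one
  through LAI_e; under severe spectral noise both degrade together.
- The NDVI-based surrogate saturates over dense canopy; the scale factor
  under-corrects exactly where NDVI carries little LAI information.
- Treatment effects are block-constant multipliers; no within-treatment
  ecology, phenology or multi-date structure is modeled.
- The plot-placement scheme guarantees separation but places plot centres
  on a coarse-pixel-aligned candidate grid, which slightly regularizes
  the plot-to-pixel matching compared to fully random field layouts.
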