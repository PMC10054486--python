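# Methods

## Model

The regressor is a UNet: a contracting path of convolutional blocks (two
3×3 convolutions, each followed by batch normalization and ReLU) with 2×2
max pooling between levels, a bottleneck block, and an expanding path of
2×2 stride-2 transposed convolutions whose outputs are concatenated with
the same-resolution encoder features (skip connections) before another
convolutional block. The head is a 1×1 convolution with **identity
activation**: no softmax, no terminal ReLU. The network therefore predicts
unbounded real values per pixel; physical non-negativity is enforced only
when carbon stocks are reported, so the training loss stays faithful to
the data. Output shape always equals input shape spatially
(patch_size must be divisible by 2^depth).

Defaults are the canonical choices — depth 4, 64 base filters doubling per
level — with every element configurable (`UNetConfig`). The desk-scale
experiments in this repository use depth 2 with 8 base filters, which is
ample for the synthetic scenes and trains in about a minute per fold on
one CPU.

All layers and their backward passes are implemented directly in NumPy
(im2col convolutions, einsum transposed convolutions, standard
batch-normalization gradients, Adam with β₁ = 0.9, β₂ = 0.999). A
finite-difference test verifies the full backward pass against numeric
gradients.

## Loss and training schedule

The loss is the **masked mean absolute error** over valid pixels; values
under the nodata mask never contribute to loss or gradient. The optimizer
is Adam with default parameters. Per fold: at most 500 epochs; training
stops when the validation loss has not improved (strictly; no minimum
delta) for 35 epochs and the weights of the best-validation epoch are
restored; a 25-epoch plateau multiplies the learning rate by 0.2, after
which the plateau counter (but not the early-stopping counter) resets.

Inputs are standardized per band with mean/SD computed on the **training
folds only**. The target is standardized the same way and the scaling is
inverted at prediction time; this keeps the monitored loss on a unit scale
so the Adam default learning rate is meaningful regardless of the biomass
range (raw Mg/ha targets would converge impractically slowly under MAE).
Batch size defaults to 32; the desk-scale experiments use 8 because with
only ~200 training patches larger batches leave too few optimizer steps
per epoch (the 100-epoch runs were visibly step-starved at batch 32).

## Cross-validation protocol

Folds are **spatial blocks**: the 16×16-patch grid is tiled into 8
contiguous rectangles (aspect chosen to match the grid), every patch of a
zone shares the zone's fold, and iteration k uses fold k for testing,
fold (k+1) mod 8 for validation and the remaining six for training. The
three sets are asserted disjoint on every iteration. Metrics (MAE, RMSE
in Mg/ha, R² = 1 − Σe²/Σ(t−t̄)²) are computed pixel-wise on valid test
pixels; the report aggregates mean ± SD over iterations. The choice of
(k+1) mod 8 as the validation fold is a determinism convention; rotating
it is equally valid.

The random-forest baselines inherit each pixel's fold from its patch, so
network and forests are compared on identical, leakage-free splits.
Forests are maximally grown, use floor(√F) candidate features per split,
and the tree count (250 vs 500) is chosen on the validation fold; ties
prefer 250.

## Engineered features

- **PC1**: projection onto the leading eigenvector of the band covariance
  estimated over valid pixels; sign fixed so the first band's loading is
  ≥ 0. All textures are computed on this plane.
- **GLCM** (5×5 window; at 100 m resolution this is a 500 m × 500 m
  footprint): gray levels quantized to 32 bins by global min–max;
  symmetric co-occurrence counts; 4 offsets at distance 1 (0°, 45°, 90°,
  135°); the eight statistics (mean, variance, homogeneity, contrast,
  dissimilarity, entropy, angular second moment, correlation) computed
  per offset and averaged; reflect padding at borders. Conventions for
  degenerate windows: correlation ≔ 0 when a marginal variance vanishes;
  a constant window yields contrast 0, homogeneity 1, second moment 1,
  entropy 0. Entropy/ASM are computed from per-entry multiplicities of
  the pair multiset, avoiding the 32×32 matrix per window; a brute-force
  dictionary enumeration in the test suite checks exact agreement.
- **Wavelets**: three-level 2-D discrete wavelet decomposition, Coiflet
  family of order 1, symmetric signal extension; the horizontal, vertical
  and diagonal detail images of each level (9 planes) are replicated back
  to the pixel grid by nearest-neighbour upsampling (pixel r →
  coefficient r // 2^level) so they serve as per-pixel predictors.
- **Spectral indices**: a plain-text registry of rational band
  expressions, shipped with 11 standard indices computable from the 10
  retained bands (NDVI, GNDVI, NDWI, NDMI, EVI, SAVI, three red-edge
  normalized differences, CI-red-edge, MSI). Division-by-zero pixels are
  set to 0 and counted in the per-plane provenance. The source studies'
  exact 132-variable and 42/11-index inventories are not fully
  enumerable; the shipped sets approximate their structure (competitor 1:
  bands + indices + GLCM, 29 columns; competitor 2: indices + GLCM +
  wavelets, 28 columns) and are user-extensible.

## Geodata conventions

Square pixels; origin = map coordinate of the top-left pixel corner; rows
grow southward; 0-based row-major indices; half-open windows. A pixel is
inside a polygon iff its center is. Reflectance = DN / 10,000; negative
digital numbers outside the nodata mask are a hard error. Down-sampling
to the 100 m training grid uses block averaging over valid pixels (an
all-invalid block becomes nodata); the kernel is a package choice — the
upstream processing chain is not specified. Up-sampling for 10 m
inference is bilinear with nearest-valid fill under the mask.
Scene/target co-registration is verified (same grid, origins within half
a pixel) rather than silently warped. Rasters are stored as TIFF with the
georeferencing in a JSON `ImageDescription` tag and NaN as nodata.
Reprojection between coordinate systems, atmospheric correction and cloud
masking are out of scope (inputs are assumed cloud-free L2A-style
products on a shared CRS).

## Carbon accounting

Predictions are clamped to ≥ 0 at this stage only. A 10 m raster is tiled
into 10×10-pixel hectare cells; each full cell contributes its
valid-pixel mean (Mg/ha) × 1 ha; margin blocks narrower than a cell
contribute their mean scaled by their true geometric area fraction, so
ragged edges never inflate totals. Above-ground carbon = 0.5 × total dry
biomass; the root correction multiplies by (1 + root fraction), 1.3 at
the default 0.3 (appropriate for temperate oak forest). Internal values
are double precision; rounding to whole tons happens only in the rendered
report.

## Synthetic scenes

The generator draws a Gaussian random field, smooths it at a configurable
correlation length (default 8 px), and quantizes it at class-fraction
quantiles into landcover classes (default 4: water, bare/urban,
grassland, forest) — giving contiguous regions with exact area fractions.
Bands are class-specific mean reflectances (plausible L2A magnitudes)
plus per-band Gaussian noise (SD 0.01, clipped to [0, 1.5]). Biomass is a
**known, configurable function of the realized bands**: by default affine
in the NDVI band ratio with class-specific intercepts (0/0/30/120 Mg/ha,
slope 180), plus Gaussian noise (default SD 10 Mg/ha, a magnitude
consistent with the ~20 % relative error quoted for the 100 m biomass
product), clipped to ≥ 0; nodata is injected independently in scene and
target (default 2 %). One master seed spawns independent substreams for
field, band noise, biomass noise and nodata, and identical seeds give
bit-identical rasters.

What the generator does **not** emulate: topography, phenology and
acquisition geometry, sensor point-spread functions, spatially correlated
retrieval error in the biomass product, and biomass signal that exceeds
the information content of a single pixel's spectrum. The last point
matters when reading the paired model table: because synthetic biomass is
(noise aside) a per-pixel function of the bands, per-pixel random forests
are near-ideal estimators there and can outscore the network; the
network's practical advantages (no feature engineering, spatial context,
one inference per patch) are not what the synthetic benchmark measures.
Passing recovery tests shows the pipeline is correct and unleaked, not
that the network dominates on real scenes.

## Desk-scale problem sizes

The repository's experiments are sized for a single CPU: recovery runs
use a 256×256 scene at 100 m (256 patches, 8 zones), a depth-2/8-filter
network, ≤ 100 epochs at batch 8, and evaluate the first cross-validation
iteration; the paired four-row comparison uses a 128×128 scene, 60
epochs, and caps forest training at 3000 sampled pixels. The noisy-case
benchmark compares held-out MAE against the Gaussian MAE floor
σ·√(2/π) ≈ 7.98 Mg/ha at σ = 10.

## Known limitations

- No reprojection; inputs must share a CRS. Pixel sizes are scalar
  (square pixels).
- The checkpoint format stores the standardizer with the weights; a
  checkpoint predicts only scenes with the channel count it was trained
  with.
- Batch-normalization running statistics are updated with momentum 0.1;
  very short trainings evaluate with partially converged statistics.
- The hectare grid of a carbon report covers whole cells; the margin
  contribution appears in the totals but not in the per-cell mean grid.
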