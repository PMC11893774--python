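# Methods

## Scope and data model

`densimap` models community wood density of mature closed-canopy forest
stands as a function of location and environment, and audits the downstream
carbon-accounting consequences of replacing stem-level density knowledge
with progressively coarser summaries. The working unit is the plot: a
georeferenced inventory of stems ≥ 10 cm diameter at breast height, each
carrying a (possibly partial) taxonomic determination. All densities are
oven-dry mass over green volume, g cm⁻³.

## Density assembly

Stems are matched to a reference database of taxon mean densities by the
most specific rank available: species, else genus, else family. Stems with
no match at any rank receive the unweighted arithmetic mean of the plot's
matched stems (`match_level="plot"`); this fallback is deliberately not
basal-area weighted, and is configurable in principle via the summary
pipeline. A plot where nothing matches raises rather than guessing.

Stand summaries: WD₁ averages over taxonomic *entities* — a fully
identified species, a genus with indeterminate species (keyed per genus), a
family with indeterminate genus (keyed per family), and one pooled
fully-unidentified set — each entity contributing the mean assigned density
of its stems. WD₂ averages over stems, WD₃ weights by basal area π(D/2)²
computed from the measured diameter at face value (no taper or buttress
correction). Census filters run in a fixed order: the diameter threshold
first, the ≥ 80% genus-identification filter second (the identification
fraction is therefore computed on censused stems only), with the 80%
boundary inclusive.

## Environmental covariates

MCWD starts the monthly water-balance recurrence at the wettest month
(ties broken to the earliest calendar month): wb[m] = (P[m] − PET[m]) +
min(wb[m−1], 0), and reports min(min(wb), 0). The clamp at zero treats the
statistic strictly as a deficit — a year in surplus every month reports 0 —
and is switchable (`clamp=False`) because an unclamped reading of the
minimum balance is also defensible.

Texture1 = ln(Sand/Clay), Texture2 = ln(Silt/Clay); the raw API rejects
zero fractions, while gridded extraction floors fractions implicitly by
construction of the soil layers. Slope is the mean of central-difference
gradient magnitudes (degrees) and rugosity the SD of elevation, both within
a 100 m-radius buffer of cells whose centers fall inside it; grid-scale
rugosity layers are instead a 3×3 neighbourhood SD of the coarse elevation
layer, a deliberately coarser source whose provenance differs from
plot-level buffers. HAND is always consumed as a supplied layer, never
derived from flow routing.

The collinearity screen applies caller-forced drops first (the default
pipeline discards slope and annual precipitation, each a member of an
|r| > 0.7 pair), then greedily removes, from any remaining high-|r| pair,
the variable participating in more such pairs, breaking ties toward the
later variable in the canonical covariate order. VIFs (1/(1−R²) of each
retained variable on the others) are reported and flagged at ≥ 4 but never
auto-dropped.

## Model ensemble

Six models: {forest, smooth_additive} × {spatial, environment, both}.

**Forest.** scikit-learn `RandomForestRegressor`; hyperparameters selected
by out-of-bag mean squared error over the full 7 × 10 grid (m_try 2–8 ×
100–1000 trees in steps of 100), ties resolving to fewer trees then smaller
m_try; combinations exceeding the feature count are skipped with a warning.
Cross-validation refits use hyperparameters frozen from a single tuning on
the full data — nested per-fold retuning is available by omitting them, but
a single tuning mirrors standard practice and keeps desk-scale runtime.

**Smooth additive model.** Implemented in-package (`densimap.smooth`):
univariate cubic P-splines of basis dimension 9 (quantile-placed knots,
second-difference penalty, sum-to-zero constraint via null-space
reparameterisation) for each environmental variable; CEC and pH enter
jointly as one isotropic bivariate smooth of dimension 9 to capture their
interaction; longitude and latitude (degrees, unprojected) enter as a
single interacting isotropic surface of basis dimension 50. Bivariate
smooths are low-rank Gaussian radial-basis surfaces: k-means centers on the
standardised plane, bandwidth = median inter-center distance, ridge penalty
on the radial coefficients and an unpenalised linear plane. Per-term
smoothing parameters minimise GCV = n·RSS/(n − tr(A))² by coordinate
descent over a log-spaced grid (two sweeps, 11 points over 10⁻⁴–10⁶); GCV
stands in for an exact restricted-likelihood criterion and the choice is
recorded in `fit_diagnostics`. Out-of-range prediction uses flat
extrapolation (covariates clipped to the training hull), which keeps grid
predictions bounded.

**Ensemble.** Unweighted mean of the member predictions, inter-model SD
with n−1 denominator. No skill weighting, by design.

**Importance.** Sampling-based Shapley values: per iteration, a random
feature order and one background draw per observation; features switch from
background to observed values along the order and marginal prediction
changes accumulate. Contributions per iteration sum exactly to
f(x) − f(background), so averaged contributions satisfy additivity against
the per-observation baseline by construction. The background is a 200-row
sample of the supplied data (configurable). Global importance is the mean
absolute contribution.

## Validation

Display regions: five lowland regions plus Atlantic forest, Andes
(elevation > 1200 m, overriding location) and dry forests (annual
precipitation < 1000 mm among non-montane plots). Cross-validation clusters
keep the five lowland regions and pool Atlantic/Andes/Dry into a sixth.

Metrics: RMSE; Pearson correlation (NaN when either vector is constant);
coefficient of determination 1 − RSS/TSS about the held-out observed mean,
negative when predictions underperform that mean. Headline statistics are
medians across folds; per-fold values are retained. Null baselines are the
training-mean predictor and a with-replacement random draw from the
training response (the sampling scheme is a package choice; without
replacement is indistinguishable at these sizes).

Residual spatial autocorrelation: Moran's I with inverse-distance weights,
zero self-weight, distances floored at half the minimum nonzero distance to
tolerate coincident plots; one-sided p from 999 permutations.

Regional refits compare, within each region of ≥ 30 plots, predictions of a
region-trained model against the dataset-trained model by Pearson
correlation.

## Applicability

Subsample sensitivity refits the model specification on n half-samples drawn without
replacement, takes the per-plot SD of the prediction ensemble, relates it
to each covariate by locally-weighted polynomial regression (tricube
weights, span 0.75, degree 2), and flags covariate intervals where the
fitted curve exceeds 0.05 g cm⁻³. The package default is n = 1000 refits;
the test suite and the acceptance script use n = 200 with a 100-tree
forest, a problem size at which the per-plot SD estimate is already stable
to well under the 0.05 flagging threshold.

The dissimilarity index standardises features by training mean/SD
(unweighted by importance), divides the nearest-training-point Euclidean
distance by the mean pairwise training distance (exact up to n = 2000,
otherwise 10⁶ random pairs), and defines the area of applicability by
Q3 + 1.5·IQR of the fold-aware training DI (each training point scored
against its nearest neighbour outside its own fold, for both fold designs).
The literal reading "1.5 × IQR" of the threshold rule is available as
`rule="1.5iqr"`; the two differ materially and the whisker rule is the
default because the DI calibration it derives from is a boxplot-outlier
construction. Quartiles use linear interpolation. Note the threshold is
*not* monotone in every DI value (raising a value below Q1 lowers it);
tests assert the properties that actually hold (monotone in the maximum,
scale-equivariant).

## Mapping

Predictions run per grid cell on cell-center coordinates; masking sets
non-forest cells to missing (−9999 in the text rasters, NaN in memory) and
cells outside the AOA are blanked in the headline ensemble layer while an
unmasked companion layer is retained. Masking is idempotent. Rasters are
ESRI ASCII grids — a plain-text, tool-agnostic format — with cell-center
registration and row 0 southernmost in memory.

## Carbon audit

AGB = a (ρ D² H)^b with a = 0.0673, b = 0.976; ln H = c₀ − E + c₁ ln D +
c₂ (ln D)², c = (0.893, 0.760, −0.0340); carbon fraction 0.456. All
coefficients live in `AllometryConfig`, never in logic. E (environmental
stress) is an input and defaults to 0 on synthetic data. Plot-wide
scenarios substitute a single ρ into every stem rather than rescaling
totals, because the allometry consumes ρ inside the power law. Percent
errors are absolute; scenario summaries are medians with interquartile
ranges, and the per-model vs ensemble distinction is reported by passing
whichever prediction vectors are of interest.

## Synthetic generator

The generator emulates what the analysis assumes, not forest dynamics:

- Covariates are Gaussian-filtered white noise (kernel width 5 cells)
  rescaled to field-plausible ranges; sand/silt/clay are normalised to sum
  to 100. The default grid is 60×60 cells of 0.05°, eight contiguous region
  blocks, forest on 90% of cells.
- The truth surface is lo + (hi−lo)·logistic(β₀ + β_lon z(lon) +
  β_cec z(CEC) + β_tex z(Texture1)), bounded in (0.3, 0.95), with a
  longitude-dominant default (β = 1.5, −0.6, 0.4) so the west-to-east
  density gradient is the leading signal.
- Plots sit at distinct forest cells; community composition is drawn from
  the species pool with weight (|ρ_s − target| + 0.01)⁻³ around
  target = truth + N(0, noise_sd), which makes the expected basal-area
  weighted density of a large plot equal the stored truth (the exponent is
  chosen so the large-plot mean is within 0.01 of target across the pool).
- Diameters are lognormal truncated at the 10 cm census threshold
  (10·exp|N(0, 0.5)|). The real diameter distribution is unknown beyond the
  threshold; this is a stand-in, not an inference.
- Identification levels are assigned per stem with species/genus
  probabilities defaulting to the observed census rates (85.1% / 95.4%);
  the remainder splits evenly between family-only and fully unknown.
  Unidentified stems keep a true density for plot-level truth but expose
  nothing to the matcher.
- Defaults: 400 plots, 120 stems/plot expected, noise_sd 0.05 g cm⁻³, plot
  areas uniform on 0.25–1.0 ha (a compact central slice of realistic plot
  areas; area only rescales carbon totals).

What the generator does **not** emulate — realistic floristics and spatial
turnover of composition, dispersal limitation, measurement error in
covariate layers (regression dilution), intra-specific density variation,
and non-stationary environment–density relationships. Passing tests
therefore demonstrate that the machinery recovers a known signal under the
stated noise model, not that real-forest predictions achieve comparable
skill; the spatial cross-validation contrast (interpolation r² ≈ 0.9 vs
near-zero or negative extrapolation r² per model) is the qualitative
behaviour expected to carry over.

## Numerical choices and degenerate inputs

Zero-variance vectors: correlation is NaN (detected by exact range, not
floating SD); r² is NaN only when the observations are constant. Moran's I
raises on constant residuals. Coincident coordinates get floored distances.
The additive model adds a 10⁻⁹ ridge to the normal equations for numerical
safety; spline bases require ≥ 4 unique covariate values and raise a named
error otherwise. Forest tie-breaks are deterministic (fewer trees, then
smaller m_try). All stochastic stages take explicit seeds; fixed seeds
reproduce outputs bit-identically.

## Known limitations

- The additive model's GCV coordinate descent can stop in a local optimum;
  two sweeps over an 11-point grid proved stable on these problem sizes but
  is not a global optimiser.
- The Shapley estimator's variance decays as 1/√(iterations); global
  rankings stabilise quickly but per-observation values at small iteration
  counts retain Monte-Carlo noise.
- Leave-one-cluster-out folds inherit whatever cluster imbalance the data
  carry; no blocking-distance optimisation is attempted.
- Problem sizes in tests and the acceptance script (e.g. 200 subsample
  refits, 15–20 Shapley iterations, 100–500 trees) are the package's
  desk-scale defaults for the synthetic study; production runs on real data
  would raise them.
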