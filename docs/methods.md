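# Methods

This note documents the models, conventions and numerical choices
behind `uavpheno`: what the simulation emulates, how segmentation and
aggregation are defined, what the statistics mean, and where the
genuinely open design choices were settled.

## 1. The analysis problem

A replicated cereal trial (wheat, durum, barley, triticale) is imaged
on seven dates between 94 and 175 days after sowing (DAS) with a
six-band camera (450, 530, 670, 700, 740, 780 nm; band symbols B, G,
R1, R2, NIR1, NIR2). For every plot and date the pipeline extracts the
vegetation-only mean reflectance per band, computes seven vegetation
indices, aggregates them over time, and regresses three bioethanol
phenotypes on them: total biomass dry weight *W* (kg/m²), enzymatic
sugar release *S* (µl glucose/mg straw), and theoretical ethanol yield

  *E* = *S* · 0.511 · (*W* · 10000) / 1000   [m³/ha]

where 0.511 is the stoichiometric glucose→ethanol mass fraction, 10⁴
converts kg/m² to kg/ha, and 10³ sets the per-hectare yield scale.
The literal formula carries an L/ha label in some sources while every
reported value is on the m³/ha scale the formula actually produces;
the package computes the formula verbatim and labels the output m³/ha.
The factor 0.511 is a named, overridable parameter
(`EthanolParams.conversion_factor`).

## 2. Trial design and geometry

`generate_trial_design(n_accessions, n_blocks, plots_per_block)` builds
a randomized complete block design: within each block a seeded
permutation assigns every accession to one of the available positions;
surplus positions are *empty plots*, exported in tables but excluded
from analysis. Defaults reproduce the reference trial scale: 66
accessions (the bundled panel: 26 bread wheat entries, 11 durum, 21
barley, 10 triticale, with Cayuga and Caledonia present twice under
distinct IDs) × 3 blocks × 78 positions = 234 plots in 10 rows per
block.

Coordinates are planar meters, origin at the raster's top-left corner,
y increasing downward, row-major pixels with 0-based indices. Plot
membership of a pixel follows the pixel-center-inside rule. Desk-scale
geometry defaults — 0.60 m × 0.45 m plots, 0.30 m inter-plot and
0.50 m inter-row spacing, rendered at a ground sampling distance (GSD)
of 0.01 m/px (≈ 60 × 45 px per plot) — keep a seven-date series of
full-trial rasters in the seconds range; the native 5.41 mm GSD of the
reference camera/altitude is supported but not the default.

## 3. Ground-truth simulation

The generator provides known truth for every downstream stage. It is a
statistical emulator, not a radiative-transfer model.

**Phenotypes.** Each accession receives a normal accession effect
around its species mean, shared across blocks; plots add independent
block noise; draws are clamped at zero. Species means (biomass 0.67 /
0.83 / 0.71 / 0.52 kg/m² and sugar 0.98 / 0.98 / 1.16 / 0.94 µl/mg for
bread wheat / durum / barley / triticale) reproduce the observed
species ordering — durum heaviest, barley most saccharifiable,
triticale lowest on both. Spreads (accession sd 0.20 kg/m² and
0.10 µl/mg; block sd 0.07 and 0.05) were fixed once so that
accession-level ranges roughly span 0.26–1.40 kg/m² and
0.77–1.36 µl/mg. *E* is computed exactly from *W* and *S*.

**Phenology.** Anthesis start is uniform on [110, 160] DAS per
accession and the window length uniform on [10, 20] days, matching the
observed earliest/latest starts.

**Reflectance.** A plot's appearance is driven by three scalars:

* *greenness* g(d): logistic rise (midpoint 25 d before anthesis
  start, scale 8 d), ≈ 1 through anthesis, exponential senescent decay
  (time constant 25 d) afterwards;
* *pigment* = g · (0.6 + 0.4 · sugar rank) + jitter — sugar-rich plots
  stay greener in the visible bands;
* *structure* = 0.85 + 0.30 · biomass rank + jitter — denser canopies
  scatter more NIR (a multiplicative NIR gain).

Visible bands interpolate between a senescent straw+background
endmember (0.08, 0.30, 0.12, 0.20 for B, G, R1, R2) and a green-leaf
endmember (0.04, 0.12, 0.05, 0.15) by *pigment*; NIR bands interpolate
from (0.30, 0.32) to (0.45, 0.50) by g and are scaled by *structure*;
soil is flat 0.20–0.30. These endmembers were chosen only so that the
seven indices behave like their field counterparts: NIR-based indices
trace a bell over the season peaking around anthesis, visible indices
stay roughly flat and rise markedly at the last, senescent date
(senescence raises G relative to R1 and B of the residue+background
mixture — a modeling choice, not canopy physics). All spectra are
config-overridable on `ReflectanceModel`.

**State noise.** Pigment and structure carry two jitter components
uncorrelated with the phenotypes: a persistent per-plot offset
(sd 0.06 each — canopy architecture, position effects; does *not*
average out over dates) and an independent per-date offset (sd 0.08 /
0.04 — illumination, wind; shrinks under temporal averaging). This is
what keeps plot-level R² moderate (≈ 0.5–0.6 for the best models) and
makes multi-date aggregation genuinely informative, mirroring field
behavior.

**Canopy cover.** The vegetation fraction of a plot follows its own
logistic (midpoint 30 d before anthesis start, scale 6 d), scaled by
0.45 + 0.50 · biomass rank, relaxing to 75 % of peak after anthesis.
Vegetation pixels are placed where a spatially smoothed uniform field
(Gaussian kernel, σ = 1.5 px, wrapped so marginals stay exactly
uniform) falls below the cover value — canopies form patches rather
than salt-and-pepper speckle, and the placement is monotone in cover
under a fixed seed. Patches smaller than `min_patch_px` (4 px, the
segmentation object-filter default) are suppressed at render time:
sub-centimeter free-standing vegetation fragments are not a feature of
real canopies at this GSD, and their absence makes noise-free
segmentation exactly invertible. Per-band i.i.d. Gaussian pixel noise
(sd 0.015) is added last; reflectances are clipped to [0, 1].

**Seeding.** One integer seed expands into named substreams (design /
phenotypes / phenology / per-date, per-plot rendering) via
`numpy.random.SeedSequence`, so each stage is independently
reproducible and regeneration is byte-identical.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: radiative transfer and BRDF,
illumination gradients, shadows, band misregistration, weeds,
inter-plot canopy overlap, lodging, and any nonlinearity in the
VI–phenotype link. Results on synthetic scenes bound the pipeline's
correctness, not the field-scale predictive power of the indices.

## 4. Segmentation (per-plot OBIA)

Each plot is thresholded independently on a per-pixel feature — excess
green (default) or NDVI — using Otsu's method: the sample is
histogrammed into `n_bins` (256) equal-width bins over its observed
range and the interior bin edge maximizing the between-class variance
w₀w₁(μ₀−μ₁)² is returned; ties break toward the lower edge; fewer than
two distinct values is a degenerate-input error. The class with the
higher feature mean is vegetation (greenness features increase with
vegetation). Connected components smaller than `min_object_size`
(4 px, 8-connectivity, strict less-than) are removed — the object-based
approximation of segmentation into homogeneous objects.

A plot is flagged **low-cover** (all-background mask, missing spectra
downstream, never biased means) when the two class means are closer
than `min_separation` = 0.10 feature units, or the vegetation fraction
is below `min_fraction` = 0.005, or the sample is degenerate. The 0.10
floor sits between the ≈ 0.06 split Otsu finds in pure soil noise and
the ≥ 0.2 vegetation–soil contrast, so bare and empty plots flag
themselves. Band means are computed over vegetation pixels only, in
float64, with NaN pixels excluded from numerator and count.

## 5. Vegetation indices

On the vegetation-only plot-mean reflectances (mean-then-index; a
per-pixel mode exists for the segmentation feature only):

| index | formula | region |
|---|---|---|
| ExG | 2G − R1 − B | visible |
| VIgreen | (G − R1)/(G + R1) | visible |
| TCI | 1.2(R2 − G) − 1.5(R1 − G)·√(R2/R1) | visible |
| NDVI | (NIR1 − R2)/(NIR1 + R2) | NIR |
| GNDVI | (NIR2 − G)/(NIR2 + G) | NIR |
| MCARI | [(NIR1 − R2) − 0.2(NIR1 − G)]·(NIR1/R2) | NIR |
| MSR | (NIR1/R2 − 1)/(√(NIR1/R2) + 1) | NIR |

NDVI pairs NIR1 with the red-edge band R2 and MCARI is built on
NIR1/R2/G — these follow the camera's filter set rather than the
classical red/green wavelengths of the literature forms. Ratio indices
require strictly positive bands; violations yield a missing value for
that index only, and denominator zeros never produce infinities.

## 6. Temporal scenarios

* **TS-1** — the raw values of one flight date (identity projection);
* **TS-2** — unweighted mean over flights inside the accession's
  anthesis window, inclusive at both ends. If no flight falls inside,
  the two flights bracketing the window midpoint are averaged and the
  row is flagged `fallback` (with the default schedule this cannot
  trigger; the flag lets analysts exclude such rows when it can);
* **TS-3** — unweighted mean over all available dates.

Missing values are ignored (contributing dates are recorded);
aggregation is invariant to input row order; anthesis windows are
accession-level, as phenology is recorded per accession.

## 7. Statistics

**Regression.** `VIPhenotypeModel` is plot-level ordinary least
squares of one phenotype on one aggregated VI (missing pairs dropped;
≥ 3 pairs and non-zero VI spread required). *R*² is the squared
Pearson correlation (defined as 0 for a flat response), RMSE the root
mean squared residual in phenotype units. Correlation categories:
low < 0.50 ≤ moderate < 0.60 ≤ high, boundaries inclusive upward.
Slope significance is a t-test at α = 0.05; across the full
VI × scenario × phenotype grid (`scan_models`) p-values are reported
raw, with no multiple-testing correction — treat the stars as
descriptive.

**ANOVA.** `species_anova` runs a one-way F-test across species
(groups with < 2 plots excluded with a warning), Tukey's HSD at
α = 0.05 for pairwise comparisons (with exactly two groups the F-test
itself decides the single pair), and an insert–absorb compact letter
display with 'a' on the highest mean.

**Ranking.** Plot-level predictions from a fitted model are averaged
per accession, sorted descending (ties by accession id), observed
accession means attached for validation, plot-level prediction RMSE
reported. Accessions with no non-missing plots are omitted with a log
message.

## 8. Pipeline and reproducibility

`RunConfig` (YAML-loadable; CLI flags override) validates before any
compute: strictly increasing dates, a known segmentation feature, and
recognized reflectance/geometry overrides. `run_pipeline` writes every
stage output under one run directory plus a manifest (config hash,
seed, package version, per-stage row counts); identical configs yield
byte-identical CSVs. Plot tables export *all* positions — one row per
plot and date, 234 × 7 by default — with empty plots carrying missing
band fields; analysis stages exclude them. Rasters are written as
six-page float32 TIFF with a JSON metadata block (geotransform, band
wavelengths, DAS tag); reading validates the six-band contract and
never rescales reflectance. Plot layouts travel as GeoJSON in planar
meters.

## 9. Known limitations

* The optical model is a two-endmember mixture with scalar state; it
  cannot probe index behavior outside the convex hull of its
  endmembers.
* Biomass and sugar enter the spectra through within-trial *ranks*, so
  absolute calibration transfer between trials is out of scope.
* The empty-window TS-2 fallback and the low-cover flag are reported
  but not modeled statistically (no missingness correction).
* Regression is simple OLS at plot level: no spatial autocorrelation,
  block effects or mixed models, and no cross-validation beyond what a
  user builds from the tables.
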