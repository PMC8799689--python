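# Methods

This note documents the model implemented by `cerramap`, the default
parameters and the reasons behind them, what the synthetic data generator
does and does not emulate, and the numerical choices that affect results.

## 1. Classification scheme

Thirteen terminal classes in a two-level hierarchy:

| Formation | Physiognomies |
|---|---|
| GRA (grassland) | CLU campo limpo úmido, CS campo sujo, CAMR campo rupestre |
| SAV (savanna) | CSS cerrado sensu stricto, CERR cerradão-like dense savanna, V vereda |
| FOR (forest) | C ciliary/riparian forest, MG gallery forest |
| other covers | PAST pasture, PF planted forest, A agriculture, W water, NV non-vegetated |

Stage 1 discriminates the 8 formation-level classes (GRA, SAV, FOR and
the 5 other covers); stage 2 splits each native formation into its
physiognomies. Other covers terminate at stage 1. Codes: nodata −1,
unclassified 0, classes 1–13.

## 2. Feature spaces

Per scene (month) the optical bands are complemented by per-scene NDVI,
EVI2, SAVI and SWIR2:SWIR1; indices are computed per scene *then*
composited, because the annual variance of an index requires per-scene
values and one consistent path avoids median-of-ratio vs ratio-of-median
ambiguity. SAR VH/VV statistics are taken in dB; the VH:VV ratio is
formed per scene in linear σ⁰ power (10^(dB/10)) and then averaged —
ratios of dB values would be differences and are meaningless.

Statistics per layer: annual/wet/dry composites (optical median, SAR
mean), annual variance (n−1 divisor, NaN below 2 observations), optional
wet/dry texture (sample sd in a ~1-ha moving window, truncated at edges),
and Horn-gradient terrain slope in degrees. The dry season is the set of
months whose climatological precipitation is strictly below 100 mm; the
default climatology makes that April–September.

Seven configurations: **F6** is the reference space (seasonal + variance
optical + SAR + slope). **F1** uses a Landsat-8-like profile (no red-edge
bands) at 30 m; **F2** annual statistics only; **F3** drops SAR; **F4**
drops annual variance; **F5** equals F6 with burned-reference masking
off; **F7** adds texture. Scene filtering drops optical scenes with cloud
fraction ≥ 0.7 and burns remaining cloud masks into the values as NaN;
composites use only unmasked observations. Everything is nearest-
neighbour resampled to the configuration's target grid (20 m, 30 m for
F1), with the target grid kept inside the source extent.

## 3. Reference data

Field sites become pixels by the pixel-centre-in-geometry rule. Vereda
and gallery-forest sites sample narrow linear features and take a fixed
12 m buffer (usually one 20 m pixel); other savanna/forest physiognomies
default to 30 m within an allowed 20–40 m; grassland sites must be
delineated polygons (their within-site heterogeneity makes a fixed buffer
unsafe). Pixels claimed by zones of different classes are discarded.
Pixels burned in any month of the imagery period are flagged and excluded
from training and validation whenever the active feature space has burn
masking enabled (all except F5); the per-formation percentage reduction
is reported.

## 4. Two-stage ensemble

Both stages use untuned random forests with 100 trees (only the tree
count is set; tuning is deliberately absent so that results measure the
features, not the tuning). The routine:

- **Outer repeats** (default 10): withhold a stratified ~20 % of zones
  per class (`max(1, round(0.2·n))`) for validation.
- **Inner runs** (default 50): each trains on a fresh random 80 % of the
  remaining pool zones (≥ 1 zone per class; the draw is repeated if a
  class drops out) and predicts every valid pixel.
- **Voting**: over all outer × inner runs, a pixel's class must win a
  strict > 50 % share of runs. Stage-1 failures are unclassified;
  stage-2 failures fall back to the stage-1 formation. The winning share
  (in %) is the per-pixel classification probability.
- **Seeding**: a master `SeedSequence` fans out per-outer, then
  per-(split/stage-1/stage-2), then per-run streams, so any sub-result is
  reproducible and seeds never collide. Forest seeds are derived as
  `generate_state(1)[0] % 2^31`.

Per-run accuracies are computed at two levels: stage-1 OA on each run's
unused pool zones, and combined stage-1+2 OA on the outer repeat's
withheld zones, where a wrong formation, a formation-level stall or a
wrong physiognomy all count against the run.

## 5. Vereda rule

Veredas are palm stands embedded in moist grassland. A mapped vereda
pixel farther than 100 m (Euclidean centre-to-centre distance) from the
nearest campo limpo úmido pixel is ecologically implausible and is
replaced by the modal class among {CSS, CERR, C, MG} in a 5×5 (1 ha)
window of the *original* map (a simultaneous pass; ties resolve in that
fixed order; pixels with no candidate in the window stay and are
counted).

## 6. Assessment

- Confusion matrices keep unclassified pixels in a separate rejection
  row; UA/PA with empty rows/columns are NaN, never 0.
- Run distributions are summarized as median and IQR (P75−P25, linear
  interpolation); configurations are compared by one-way ANOVA plus
  Tukey HSD at α = 0.05.
- Areas use the stratified estimator with map-class strata: weights are
  mapped-area proportions, `p̂_k = Σ_i W_i n_ik/n_i·`,
  `SE = sqrt(Σ_i W_i² p_i(1−p_i)/(n_i·−1))`, CI = 1.96·SE·A. Strata with
  ≤ 1 validation pixel are an error (variance undefined), never silently
  dropped by the estimator itself.
- Burned-area products are scored on period unions: CE = FP/(TP+FP),
  OE = FN/(TP+FN), bias = (TP+FP)/(TP+FN), with an optional
  "all-unburned" CE = FP/(FP+TN) variant and an optional filter removing
  reference scars (8-connected) below an area threshold (e.g. 0.5 km²)
  before scoring.

## 7. Synthetic scenes

The generator produces, from one seed: smoothed-Gaussian terrain with an
exact relief amplitude; a landscape with drainage-line corridors (campo
limpo úmido lines of width 5 containing 2×2 vereda stands, gallery-forest
lines of width 2), slope-biased rupestrian grassland and smoothed-field
upland patches, with realized class fractions calibrated to within ±20 %
of the requested fractions (for fractions ≥ 0.02); monthly optical and
SAR scenes that take each class's wet or dry anchor spectrum by the
month's season plus N(0, sd) noise; cloud blobs (optical only); and
elliptical burn scars concentrated in the late dry season, which impose a
char spectrum for the burn month and the following month.

Default study conditions: 200×200 pixels at 20 m, 12 monthly scenes,
signature noise sd = 0.010 (anchor spectra spaced ≥ 3 sd), no clouds, no
burns unless requested, 10 sites per class. The `phenology_scene_config`
variant gives physiognomies within a formation identical mid-season
spectra that differ only in seasonal amplitude — the condition under
which annual-only features (F2) are expected to fail and seasonal
features (F6) to succeed.

What the scenes do **not** emulate: geolocation error, mixed pixels,
atmospheric and BRDF effects, within-class spatial autocorrelation of
reflectance, inter-annual variability, SAR speckle statistics (noise is
Gaussian in dB) and label noise in the reference data. Consequently
absolute accuracies here are far higher than any real-world deployment;
the package's claims are about contracts and directions (e.g. F6 ≥ F2 on
phenology-driven scenes), not magnitudes. Note also that because
composites are per-pixel *medians* over 12 months, a 2-month char episode
is usually absorbed and burn masking shows little accuracy benefit on
these scenes; the masking contract is therefore verified by exact
exclusion counts plus a one-sided no-harm check.

## 8. Numerical and I/O choices

- All in-memory nodata is NaN; rasters serialize to TIFF with the grid
  geometry and nodata sentinel stored as a JSON header in the TIFF
  description tag (round-trips exactly); zones serialize to plain
  GeoJSON.
- Zone splitting, training draws and all stochastic generation use
  NumPy `Generator`/`SeedSequence` streams exclusively.
- `estimate_areas` and `texture_layer` are vectorized; the vereda rule
  visits only offending pixels.
- Problem sizes in tests (60–200 px grids, 1–5 outer × 3–10 inner runs)
  are the package's own choices to keep the suite under a few minutes
  while spanning every code path; the defaults (200×200, 10×50, 100
  trees) remain the documented study conditions.
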