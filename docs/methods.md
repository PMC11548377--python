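# Methods

## The classification model

The classifier is a fixed three-node decision tree over four spectral
indices, applied per pixel inside a lake mask. It assumes its input is
*surface reflectance* — atmospherically corrected, dimensionless, nominally
in [0, 1] — in six co-registered reflective bands (blue, green, red, NIR,
SWIR1, SWIR2). Radiometric correction is upstream of this package; small
negative reflectances that correction can produce over dark water are
passed through unclipped, because clipping would bias exactly the
near-zero water signals the tree depends on.

* **Node 1 — AVI** (negated tasseled-cap wetness, `AVI = -Σ k_i R_i`)
  separates aquatic vegetation from non-vegetation. Water is the wettest
  thing in a scene; any vegetation signal depresses wetness, so vegetation
  sits above water on the AVI axis regardless of life form.
* **Node 2 — NDVI** splits vegetation into floating/emergent (canopy in
  air: strong NIR, high NDVI) versus submerged (NIR absorbed by the water
  column: NDVI near zero).
* **Node 3 — FAI** splits non-vegetation into bloom (NIR peak above the
  red–SWIR1 linear baseline) versus open water (below it). The baseline
  form is the canonical linear interpolation
  `R'_NIR = R_red + (R_SWIR1 − R_red)·(λ_NIR − λ_red)/(λ_SWIR1 − λ_red)`,
  which makes FAI invariant to a constant offset applied to all three
  bands — the property that lets it shrug off thin haze.

Every node uses a strict `>`, with ties falling to the lower branch. This
is an arbitrary but frozen convention; it makes the tree a total,
deterministic function, which the tests exploit (a pixel placed exactly on
a threshold is checkably open water).

### Sensor profiles

The wetness coefficients are instrument constants. The package ships the
standard reflectance-domain sets — Crist (1985) for TM, Huang et al.
(2002) for ETM+, Baig et al. (2014) for OLI — with nominal band centers
(TM red/NIR/SWIR1 = 660/830/1650 nm, OLI = 655/865/1609 nm). Published
wetness derivations differ (reflectance- vs DN-domain, at-sensor vs
surface), and which set a given historical analysis used is often
unknowable; `register_profile` exists so a user can pin any other set
without touching code. All sets share the structural property the tree
relies on: both SWIR coefficients negative, which profile validation
enforces.

### Thresholds

| cut | default | rationale |
| --- | --- | --- |
| `t_ndwi` | 0.0 | standard open-water cut for green/NIR NDWI; used only to extract water for calibration |
| `t_avi` | per-scene: water mean + 2 sd (fixed fallback −0.01) | open-water AVI drifts scene to scene with atmosphere and water colour, so a global constant is fragile; the water-mean statistic re-anchors it per scene, and the +2 sd offset keeps the false-vegetation rate of open water near 2.3% under Gaussian noise (mean alone would split water 50/50) |
| `t_ndvi` | 0.2 | bare-to-sparse surfaces sit below ≈0.1; 0.2 separates emergent canopies (≥0.5 typically) from submerged canopies (≈0) with margin on both sides |
| `t_fai` | 0.0 | bloom is defined as any NIR excess over the baseline |

All four cuts plus `k_sigma` live in one config-exposed dataclass and are
recorded in every map's provenance. Calibration refuses to run on fewer
than 30 water pixels rather than return a noise-dominated cut.

Whether one global AVI cut or per-scene calibration better matches a
multi-decadal archive is genuinely open; both modes exist
(`classify_batch(..., auto_avi=True/False)`), and the batch API records
which was used per scene.

### Masking

The lake boundary is applied *before* classification (pixels outside
become nodata), so terrestrial vegetation can never appear as FEAV. Cloud
and shadow screening is out of scope — the intended inputs are cloud-free
acquisitions — but any user-supplied invalid-pixel mask is honored through
the same nodata channel, and nodata propagates unchanged through every
index and the tree.

## Accuracy assessment

Confusion matrices use rows = reference, columns = predicted; overall
accuracy and Cohen's kappa are both transpose-invariant, so the convention
matters only for the per-class producer's/user's accuracies. Kappa is the
closed-form `(p_o − p_e)/(1 − p_e)`; a degenerate matrix with expected
agreement 1 raises rather than returning a number. The implementation is
cross-checked in the tests against scikit-learn's independent kappa.
Reference points are matched to predictions by nearest pixel center — one
fixed geometric convention, applied everywhere, prevents off-by-one-pixel
drift between tools. Area-adjusted accuracy estimation and kappa variance
are out of scope.

## Coverage and trends

Coverage is `count(class) / count(valid lake pixels)` — the denominator
deliberately excludes invalid pixels so masked data cannot deflate
coverage (the alternative, total lake area, would conflate cloud cover
with vegetation loss). Fractions over {SAV, FEAV, AB, OW} always sum to 1
over valid pixels. The time-series table is long-format
(year, season, class, fraction); a duplicate year–season pair is an error
and missing pairs are absent rows, never zeros. April–May maps to spring
and July–August to summer (the archive's acquisition windows); other
months follow meteorological seasons, needed when joining quarterly
water-quality records.

## Driver regressions

Coverage–driver relations are ordinary least squares with R², the
two-sided t-test on the slope, and a t-interval CI
(`FitResult.slope_ci`). A constant-y input returns slope 0, R² = 0,
p = 1 by convention; a constant-x input is an error. The seasonal
comparison uses Welch two-sample tests (robust to the unequal variances
and group sizes quarterly sampling produces) with Holm correction across
all pairs, rendered as a compact letter display (groups sharing no letter
differ at α = 0.05). Autocorrelation-aware or mixed models are out of
scope: the quarterly series here are short, and the package reports plain
OLS inference, which the simulation calibration below validates under
independence.

## The synthetic-data generators

`generate_scene` draws each pixel as its class-mean spectrum plus
independent per-band Gaussian noise (default conditions: sd 0.01 in
reflectance units, a realistic post-correction noise level for
Landsat-class surface reflectance over water). The default class spectra
are *stylized*: they keep the field-expected ordering (FEAV NIR-dominant;
SAV water-like with depressed wetness; bloom peaked above the red–SWIR
baseline; open water green-dominant) but their exact values were chosen
once so that every class mean clears its decision node by at least ~2
noise standard deviations at sd 0.01. The generator evaluates the tree on
its own noiseless spectra before emitting anything and raises, naming the
violated node, if a custom spectrum set is not separable — an untestable
fixture fails loudly at generation time rather than silently downstream.

What the generator does **not** emulate: spatially correlated noise,
mixed pixels at class boundaries, adjacency effects, sun-glint, cloud,
within-class spectral gradients (e.g. canopy density), and bottom
reflectance in shallow water. Passing tests therefore demonstrate that the
pipeline machinery is correct and noise-robust under idealized spectra —
not that the default thresholds transfer to any particular real lake,
where threshold calibration against reference data remains the user's
responsibility.

`generate_lake_timeseries` shrinks the submerged-vegetation region
linearly between two coverage fractions (rounded to whole pixels, so the
recovered series matches the requested fractions within one pixel
quantum), with a constant floating/emergent strip. `generate_env_series`
draws quarterly water quality around seasonal means taken from the study
lake — TP 0.032 mg/L in the vegetated spring vs 0.085 mg/L otherwise,
summer Secchi depth 0.35 m against ~2 m water depth — and couples coverage
to one driver as `coverage = a + b·x + N(0, σ)` (defaults a = 0.6,
b = −5 per mg/L TP, σ = 0.05), returning the true coefficients.
Concentrations are truncated at zero and Secchi depth floored at 5 cm, but
the default spreads keep truncation rare so the linear relation is not
bent; the coverage response is intentionally left unclipped so that CI
coverage and type-I calibration of the OLS inference can be verified
against an exactly linear-Gaussian truth. All generators are bit-for-bit
reproducible from their seed.

## Problem sizes

The shipped analyses and checks run at desk scale, chosen as the smallest
sizes at which the statistical statements are stable: classifier
validation on 256×256 scenes over 20 seeds; decision-tree/oracle
equivalence on 50 random scenes up to 16×16; an 8-year declining series at
64×64; regression calibration over 200 simulated 50-point series (CI
coverage and null rejection rate each). The full suite runs in well under
a minute.

## Known limitations

* The light-limitation threshold (Z_M/Z_SD > 5.17) is an empirical,
  single-lake value; it is a default, not a constant of nature, and is
  exposed as a parameter.
* Per-scene AVI calibration assumes open water dominates the NDWI-positive
  mask; in a lake almost fully covered by vegetation the calibration water
  sample may be contaminated and the fixed fallback cut is safer.
* Sub-pixel mixtures are assigned whole-pixel labels; coverage of sparse
  or patchy vegetation is resolution-limited.
* No cross-sensor harmonization is applied; comparing AVI magnitudes
  across sensors relies on the per-scene calibration absorbing the
  difference.
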