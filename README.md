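# aquaveg

Mapping aquatic vegetation and algal blooms in shallow lakes from
multiband surface-reflectance imagery — and relating vegetation coverage
to water-quality drivers.

Shallow lakes flip between a clear-water state dominated by submerged
macrophytes and a turbid state dominated by algae. Tracking which state a
lake is in, and how macrophyte coverage changes over decades, is a core
monitoring task in lake restoration. This package implements a
decision-tree pipeline for that task, aimed at people working with
Landsat-class surface-reflectance scenes (6 reflective bands: blue, green,
red, NIR, SWIR1, SWIR2) of lakes: classify every lake pixel, validate the
map, build coverage time series, and regress coverage against
environmental drivers.

## The classifier

Each valid lake pixel is assigned one of four classes — submerged aquatic
vegetation (SAV), floating/emergent aquatic vegetation (FEAV), algal bloom
(AB), open water (OW) — by a three-step decision tree over spectral
indices:

1. **AVI** (aquatic vegetation index), the negated tasseled-cap wetness
   `AVI = -Σᵢ k_λᵢ R_λᵢ` with sensor-specific wetness coefficients
   `k_λᵢ`, separates vegetation (AVI > t_AVI) from non-vegetation.
2. **NDVI** `= (R_NIR − R_red)/(R_NIR + R_red)` splits vegetation into
   FEAV (NDVI > t_NDVI; emergent canopies reflect strongly in the NIR)
   and SAV (water-attenuated NIR).
3. **FAI** (floating algae index), the NIR height above the linear
   red–SWIR1 baseline
   `FAI = R_NIR − [R_red + (R_SWIR1 − R_red)·(λ_NIR − λ_red)/(λ_SWIR1 − λ_red)]`,
   splits non-vegetation into AB (FAI > t_FAI) and OW.

The AVI cut is calibrated per scene: water is extracted with
NDWI `= (R_green − R_NIR)/(R_green + R_NIR) > 0`, and
`t_AVI = mean(AVI_water) + k·sd(AVI_water)` (default k = 2).

Map accuracy is assessed with a confusion matrix, overall accuracy
(trace/total) and Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)`. Coverage is
the per-class fraction of valid lake pixels; coverage–driver relations
(total phosphorus TP, total nitrogen TN, the light-climate ratio
Z_M/Z_SD of water depth to Secchi depth) are ordinary least-squares fits
with R² and a t-test on the slope.

## Worked example

```python
from aquaveg import (SceneSpec, generate_scene, classify_scene,
                     coverage_fraction)

scene, truth = generate_scene(SceneSpec(width=256, height=256,
                                        noise_sd=0.01, seed=2024))
classmap = classify_scene(scene)
print((classmap.labels == truth.labels).mean())
rec = coverage_fraction(classmap, date="2020-04-20")
print({k: round(v, 3) for k, v in rec.fractions.items()})
```

prints

```
0.990264892578125
{'FEAV': 0.252, 'SAV': 0.254, 'AB': 0.252, 'OW': 0.242}
```

— a noisy four-quadrant synthetic scene (equal quarters of the four
classes) is classified 99.0% correctly, and the recovered coverage
fractions land within about one percentage point of the true 25% each
(open water loses slightly to the other classes through noise-driven
commission).

The same pipeline is runnable from the shell
(`aquaveg simulate scene`, `aquaveg classify`, `aquaveg accuracy`,
`aquaveg timeseries`, `aquaveg envfit`; see `--help`), and the numbered
scripts under `analysis/` walk the full study: `01_simulate_inputs.py`
(synthetic scenes and water-quality series), `02_classify_and_validate.py`
(accuracy assessment — the published validation matrix gives overall
accuracy 93.42% and kappa 0.87), `03_coverage_timeseries.py` (declining
submerged-vegetation trend), `04_env_drivers.py` (driver regressions and
the seasonal TP contrast). Each writes its tables to `results/`.

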