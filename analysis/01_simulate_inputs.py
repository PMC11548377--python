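#!/usr/bin/env python
"""Generate the synthetic study inputs and record their design.

Real inputs for this analysis would be ~48 cloud-free Landsat spring/summer
surface-reflectance scenes (2000-2023) plus quarterly water-quality tables;
neither is redistributable here, so everything downstream runs on synthetic
stand-ins of known structure:

* a four-quadrant 6-band reflectance scene (FEAV / SAV / AB / OW) with
  per-band Gaussian noise, for classifier validation;
* an 8-year spring series in which the submerged-vegetation area shrinks
  linearly from 60% to 5% of the lake (the observed multi-decade pattern,
  compressed);
* a quarterly water-quality table (TP low in the vegetated spring, high
  otherwise; summer Secchi depth ~0.35 m) with SAV coverage linearly
  coupled to TP (slope -5 per mg/L).

Scene rasters land under scratch/ (they are regenerated on demand from the
seeds recorded in results/simulated_conditions.json); the env tables are
small CSVs under results/.
"""

import json
from pathlib import Path

from aquaveg import EnvSeriesSpec, SceneSpec, generate_env_series, generate_scene
from aquaveg.io import write_classmap, write_scene
from aquaveg.synthetic import generate_lake_timeseries

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "scenes"

SEED = 2024
SCENE = dict(width=256, height=256, noise_sd=0.01, seed=SEED)
SERIES = dict(n_years=8, sav_start=0.60, sav_end=0.05, seed=SEED, size=64)
ENV = dict(n_dates=50, slope=-5.0, coverage_noise_sd=0.05, seed=SEED)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    scene, truth = generate_scene(SceneSpec(**SCENE))
    write_scene(scene, SCRATCH / "validation_scene.tif")
    write_classmap(truth, SCRATCH / "validation_truth.tif")
    print(f"validation scene: {scene.shape[0]}x{scene.shape[1]}, "
          f"noise sd {SCENE['noise_sd']}")

    series = generate_lake_timeseries(**SERIES)
    for date, sc, tr in series:
        write_scene(sc, SCRATCH / f"series_{date}.tif")
        write_classmap(tr, SCRATCH / f"series_{date}_truth.tif")
    print(f"declining series: {len(series)} spring scenes, "
          f"SAV {SERIES['sav_start']:.0%} -> {SERIES['sav_end']:.0%}")

    env, cov, truth_coeff = generate_env_series(EnvSeriesSpec(**ENV))
    env.to_csv(RESULTS / "env_series.csv", index=False)
    cov.to_csv(RESULTS / "sav_coverage_series.csv", index=False)
    print(f"env series: {len(env)} quarterly records, true TP slope "
          f"{truth_coeff['slope']}")

    (RESULTS / "simulated_conditions.json").write_text(
        json.dumps({"scene": SCENE, "series": SERIES, "env": ENV,
                    "true_env_coefficients": truth_coeff}, indent=2) + "\n"
    )
    print(f"conditions recorded in {RESULTS / 'simulated_conditions.json'}")


if __name__ == "__main__":
    main()
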