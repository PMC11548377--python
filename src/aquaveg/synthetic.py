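"""Synthetic scenes and environmental series with known ground truth.

Real inputs for this kind of analysis are Landsat surface-reflectance
scenes and quarterly water-quality tables; neither travels with the
package.  This module generates stand-ins with *known* structure so that
every pipeline stage — indices, decision tree, accuracy, coverage trends,
driver regressions — can be exercised and verified at desk scale:

* :func:`generate_scene` builds a 6-band reflectance scene from a class
  layout and per-class mean spectra plus independent per-band Gaussian
  noise, and returns the intended class of every pixel as ground truth.
  The default spectra are stylized (class means chosen for decision-margin,
  not radiative-transfer realism) but ordered like the real classes:
  floating/emergent vegetation is NIR-dominant, submerged vegetation is
  water-like with strongly depressed tasseled-cap wetness, bloom has a NIR
  peak above the red-SWIR baseline, open water is green-dominant.
* :func:`generate_lake_timeseries` shrinks the submerged-vegetation region
  linearly across years (replaced by open water), emulating a declining
  macrophyte lake.
* :func:`generate_env_series` draws seasonal water-quality series and
  coverage values linearly related to one driver, returning the true
  coefficients for parameter-recovery tests.

Every generator is bit-for-bit reproducible from its seed.  The scene
generator *refuses* to emit a spectrum set that the decision tree cannot
separate at zero noise: it evaluates the tree on each class mean and names
the violated node, so an untestable fixture fails loudly at generation
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import DEFAULT_THRESHOLDS, Thresholds, classify_scene
from .raster import CLASS_CODES, CLASS_NAMES, ClassMap, GridGeoref, ReflectanceScene
from .sensors import BAND_NAMES, get_profile

__all__ = [
    "DEFAULT_SPECTRA",
    "SceneSpec",
    "EnvSeriesSpec",
    "SeparabilityError",
    "generate_scene",
    "generate_lake_timeseries",
    "generate_env_series",
]

#: Per-class mean reflectance, band order (blue, green, red, NIR, SWIR1, SWIR2).
#: Chosen once against the default thresholds and the TM wetness set so that
#: the noiseless scene classifies 100% correctly with comfortable margins
#: (every decision-node distance is at least ~2 noise-sd at noise_sd = 0.01).
DEFAULT_SPECTRA: dict[str, tuple[float, ...]] = {
    "FEAV": (0.05, 0.08, 0.06, 0.35, 0.20, 0.10),
    "SAV": (0.06, 0.07, 0.09, 0.09, 0.12, 0.06),
    "AB": (0.05, 0.07, 0.05, 0.12, 0.01, 0.005),
    "OW": (0.06, 0.08, 0.06, 0.02, 0.01, 0.005),
}


class SeparabilityError(ValueError):
    """A class-mean spectrum falls on the wrong side of a decision node."""


def _tree_path(spectrum: Sequence[float], sensor_id: str, thresholds: Thresholds):
    """Evaluate the three indices the tree uses on one mean spectrum."""
    profile = get_profile(sensor_id)
    r = np.asarray(spectrum, dtype=float)
    avi = -float(np.dot(profile.wetness_coefficients, r))
    red, nir, swir1 = (r[BAND_NAMES.index(b)] for b in ("red", "nir", "swir1"))
    lam = profile.band_wavelengths_nm
    frac = (lam["nir"] - lam["red"]) / (lam["swir1"] - lam["red"])
    fai = nir - (red + (swir1 - red) * frac)
    ndvi = (nir - red) / (nir + red) if nir + red != 0 else np.nan
    return avi, ndvi, fai


def check_separability(
    spectra: Mapping[str, Sequence[float]],
    sensor_id: str,
    thresholds: Thresholds,
) -> None:
    """Raise :class:`SeparabilityError` naming the first violated tree node."""
    for cls, spec in spectra.items():
        avi, ndvi, fai = _tree_path(spec, sensor_id, thresholds)
        if cls in ("FEAV", "SAV"):
            if not avi > thresholds.t_avi:
                raise SeparabilityError(
                    f"class {cls!r} violates the step-1 AVI node: "
                    f"AVI={avi:.4f} is not > t_avi={thresholds.t_avi}"
                )
            want_feav = cls == "FEAV"
            if (ndvi > thresholds.t_ndvi) != want_feav:
                raise SeparabilityError(
                    f"class {cls!r} violates the step-2 NDVI node: "
                    f"NDVI={ndvi:.4f} vs t_ndvi={thresholds.t_ndvi}"
                )
        else:
            if avi > thresholds.t_avi:
                raise SeparabilityError(
                    f"class {cls!r} violates the step-1 AVI node: "
                    f"AVI={avi:.4f} is not <= t_avi={thresholds.t_avi}"
                )
            want_ab = cls == "AB"
            if (fai > thresholds.t_fai) != want_ab:
                raise SeparabilityError(
                    f"class {cls!r} violates the step-3 FAI node: "
                    f"FAI={fai:.4f} vs t_fai={thresholds.t_fai}"
                )


def _quadrant_layout(height: int, width: int) -> np.ndarray:
    """Default layout: FEAV / SAV / AB / OW in the four quadrants."""
    labels = np.empty((height, width), dtype=np.uint8)
    h2, w2 = height // 2, width // 2
    labels[:h2, :w2] = CLASS_CODES["FEAV"]
    labels[:h2, w2:] = CLASS_CODES["SAV"]
    labels[h2:, :w2] = CLASS_CODES["AB"]
    labels[h2:, w2:] = CLASS_CODES["OW"]
    return labels


@dataclass
class SceneSpec:
    """Recipe for one synthetic scene.

    ``layout`` is an optional label raster (uint8 class codes, shape
    ``(height, width)``); by default the four classes occupy the four
    quadrants.  ``noise_sd`` is the per-band Gaussian standard deviation
    (reflectance units; 0.01 is a realistic post-correction level for
    Landsat surface reflectance over water).
    """

    width: int = 64
    height: int = 64
    spectra: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRA)
    )
    layout: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    sensor_id: str = "TM"
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    georef: GridGeoref = field(default_factory=GridGeoref)

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("scene must be at least 2x2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, spec in self.spectra.items():
            if len(tuple(spec)) != len(BAND_NAMES):
                raise ValueError(f"spectrum for {cls!r} must have 6 bands")
            if min(spec) < 0:
                raise ValueError(f"spectrum for {cls!r} has negative reflectance")


def generate_scene(spec: SceneSpec) -> tuple[ReflectanceScene, ClassMap]:
    """Build a scene from its recipe; returns (scene, ground-truth class map).

    The class-mean spectra are validated against the decision tree at zero
    noise before any pixel is drawn (see :func:`check_separability`).
    """
    layout = spec.layout
    if layout is None:
        layout = _quadrant_layout(spec.height, spec.width)
    layout = np.asarray(layout, dtype=np.uint8)
    if layout.shape != (spec.height, spec.width):
        raise ValueError(
            f"layout shape {layout.shape} != (height, width) = "
            f"({spec.height}, {spec.width})"
        )
    present = {c for c in CLASS_NAMES if (layout == CLASS_CODES[c]).any()}
    missing = present - set(spec.spectra)
    if missing:
        raise ValueError(f"layout uses classes without spectra: {sorted(missing)}")
    check_separability(
        {c: spec.spectra[c] for c in present}, spec.sensor_id, spec.thresholds
    )

    rng = np.random.default_rng(spec.seed)
    bands = np.zeros((len(BAND_NAMES), spec.height, spec.width), dtype=np.float64)
    for cls in present:
        mask = layout == CLASS_CODES[cls]
        mean = np.asarray(spec.spectra[cls], dtype=float)
        bands[:, mask] = mean[:, None]
    if spec.noise_sd > 0:
        bands += rng.normal(0.0, spec.noise_sd, size=bands.shape)

    valid = layout != CLASS_CODES["nodata"]
    scene = ReflectanceScene(
        bands=bands, sensor_id=spec.sensor_id, georef=spec.georef, valid=valid
    )
    truth = ClassMap(
        np.where(valid, layout, CLASS_CODES["nodata"]),
        georef=spec.georef,
        provenance={"generator": "generate_scene", "seed": spec.seed},
    )
    return scene, truth


def generate_lake_timeseries(
    n_years: int,
    sav_start: float,
    sav_end: float,
    seed: int = 0,
    start_year: int = 2000,
    size: int = 64,
    noise_sd: float = 0.005,
    sensor_id: str = "TM",
    feav_fraction: float = 0.05,
) -> list[tuple[str, ReflectanceScene, ClassMap]]:
    """Annual spring scenes with linearly declining submerged vegetation.

    The submerged-vegetation (SAV) area interpolates from ``sav_start`` to
    ``sav_end`` (as fractions of the lake) across ``n_years``, the freed
    area becoming open water; a constant thin floating/emergent strip
    (``feav_fraction``) sits along one shore.  Dated ``YYYY-04-20``
    (a spring acquisition).  Pixel counts are rounded, so recovered
    coverage matches the requested fractions to within one pixel quantum.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years for a series")
    for name, f in (("sav_start", sav_start), ("sav_end", sav_end),
                    ("feav_fraction", feav_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    if feav_fraction + max(sav_start, sav_end) > 1.0:
        raise ValueError("feav_fraction plus SAV fraction exceeds the lake")

    total = size * size
    n_feav = int(round(feav_fraction * total))
    out: list[tuple[str, ReflectanceScene, ClassMap]] = []
    for i in range(n_years):
        f_sav = sav_start + (sav_end - sav_start) * i / (n_years - 1)
        n_sav = int(round(f_sav * total))
        flat = np.full(total, CLASS_CODES["OW"], dtype=np.uint8)
        flat[:n_feav] = CLASS_CODES["FEAV"]
        flat[n_feav : n_feav + n_sav] = CLASS_CODES["SAV"]
        layout = flat.reshape(size, size)
        spec = SceneSpec(
            width=size,
            height=size,
            layout=layout,
            noise_sd=noise_sd,
            seed=seed + i,
            sensor_id=sensor_id,
        )
        scene, truth = generate_scene(spec)
        date = f"{start_year + i}-04-20"
        truth.provenance["date"] = date
        out.append((date, scene, truth))
    return out


@dataclass
class EnvSeriesSpec:
    """Recipe for paired water-quality and coverage series.

    Seasonal means follow the study lake: total phosphorus low in the
    vegetated spring (0.032 mg/L) and high in the unvegetated seasons
    (0.085 mg/L); summer Secchi depth around 0.35 m against ~2 m water
    depth.  Coverage is linearly related to one driver,
    ``coverage = intercept + slope * driver + N(0, coverage_noise_sd)``,
    and the true coefficients are returned for recovery tests.
    """

    n_dates: int = 24
    start_year: int = 2018
    driver: str = "TP"
    intercept: float = 0.6
    slope: float = -5.0
    coverage_noise_sd: float = 0.05
    seed: int = 0
    tp_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "spring": 0.032, "summer": 0.085, "autumn": 0.085, "winter": 0.085,
        }
    )
    tp_sd: float = 0.015
    tn_mean: float = 1.2
    tn_sd: float = 0.3
    zm_mean: float = 2.0
    zm_sd: float = 0.3
    zsd_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "spring": 0.8, "summer": 0.35, "autumn": 0.5, "winter": 0.6,
        }
    )
    zsd_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_dates < 3:
            raise ValueError("need at least 3 dates")
        if self.driver not in ("TP", "TN", "zm_zsd"):
            raise ValueError("driver must be TP, TN or zm_zsd")


_SEASON_MONTH = {"spring": 4, "summer": 7, "autumn": 10, "winter": 1}
_QUARTERS = ("spring", "summer", "autumn", "winter")


def generate_env_series(
    spec: EnvSeriesSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Quarterly environmental series plus linearly coupled SAV coverage.

    Returns ``(env, coverage, truth)``: the env table (date, season, TP,
    TN, Z_M, Z_SD), the coverage table (date, season, sav_coverage), and
    the true generating coefficients
    ``{"driver", "intercept", "slope", "noise_sd"}``.  Concentrations are
    truncated at 0 and Secchi depth floored at 5 cm; the sampling spread
    is kept small against the means so truncation is rare and does not
    bend the linear relation.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_dates):
        season = _QUARTERS[i % 4]
        year = spec.start_year + i // 4
        date = pd.Timestamp(year=year, month=_SEASON_MONTH[season], day=15)
        tp = max(0.0, rng.normal(spec.tp_mean[season], spec.tp_sd))
        tn = max(0.0, rng.normal(spec.tn_mean, spec.tn_sd))
        zm = max(0.2, rng.normal(spec.zm_mean, spec.zm_sd))
        zsd = max(0.05, rng.normal(spec.zsd_mean[season], spec.zsd_sd))
        rows.append(
            {"date": date, "season": season, "TP": tp, "TN": tn,
             "Z_M": zm, "Z_SD": zsd}
        )
    env = pd.DataFrame(rows)

    if spec.driver == "zm_zsd":
        x = (env["Z_M"] / env["Z_SD"]).to_numpy()
    else:
        x = env[spec.driver].to_numpy()
    noise = rng.normal(0.0, spec.coverage_noise_sd, size=spec.n_dates)
    coverage = pd.DataFrame(
        {
            "date": env["date"],
            "season": env["season"],
            "sav_coverage": spec.intercept + spec.slope * x + noise,
        }
    )
    truth = {
        "driver": spec.driver,
        "intercept": spec.intercept,
        "slope": spec.slope,
        "noise_sd": spec.coverage_noise_sd,
    }
    return env, coverage, truth
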