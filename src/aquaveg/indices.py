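"""The four per-pixel spectral indices: AVI, FAI, NDVI, NDWI.

AVI (aquatic vegetation index) is the negated tasseled-cap wetness,

    AVI = -sum_i k_i * R_i          (i over the 6 reflective bands)

with sensor-specific wetness coefficients ``k_i``.  Water has high wetness,
vegetation canopies low wetness, so AVI is higher over aquatic vegetation
than over open water.

FAI (floating algae index) is the height of the NIR reflectance above a
linear baseline interpolated between the red and SWIR1 bands:

    R'_NIR = R_red + (R_swir1 - R_red) * (l_nir - l_red) / (l_swir1 - l_red)
    FAI    = R_NIR - R'_NIR

with band-center wavelengths ``l``.  Surface blooms push NIR above the
baseline (FAI > 0); clear water sits below it.

NDVI = (NIR - red) / (NIR + red) and NDWI = (green - NIR) / (green + NIR)
are the usual normalized differences for vegetation vigor and open water.

All four preserve the scene's nodata footprint exactly; NDVI/NDWI pixels
with a zero denominator additionally become nodata (0/0 carries no
information and must not masquerade as a valid value).
"""

from __future__ import annotations

import numpy as np

from .raster import IndexRaster, ReflectanceScene
from .sensors import BAND_NAMES, SensorProfile, get_profile

__all__ = ["compute_avi", "compute_fai", "compute_ndvi", "compute_ndwi", "compute_index"]


def _check_profile(scene: ReflectanceScene, profile: SensorProfile | None) -> SensorProfile:
    if profile is None:
        return get_profile(scene.sensor_id)
    if profile.sensor_id != scene.sensor_id:
        raise ValueError(
            f"profile is for sensor {profile.sensor_id!r} but scene was acquired "
            f"by {scene.sensor_id!r}"
        )
    return profile


def compute_avi(scene: ReflectanceScene, profile: SensorProfile | None = None) -> IndexRaster:
    """Negated tasseled-cap wetness, per pixel.

    ``profile`` defaults to the registered profile for ``scene.sensor_id``;
    an explicit profile must match the scene's sensor.
    """
    profile = _check_profile(scene, profile)
    k = np.asarray(profile.wetness_coefficients, dtype=np.float64)
    avi = -np.tensordot(k, scene.bands, axes=(0, 0))
    return IndexRaster(avi, "AVI", georef=scene.georef, valid=scene.valid.copy())


def compute_fai(scene: ReflectanceScene, profile: SensorProfile | None = None) -> IndexRaster:
    """NIR height above the red-SWIR1 linear baseline."""
    profile = _check_profile(scene, profile)
    lam = profile.band_wavelengths_nm
    frac = (lam["nir"] - lam["red"]) / (lam["swir1"] - lam["red"])
    red, nir, swir1 = scene.band("red"), scene.band("nir"), scene.band("swir1")
    baseline = red + (swir1 - red) * frac
    return IndexRaster(nir - baseline, "FAI", georef=scene.georef, valid=scene.valid.copy())


def _normalized_difference(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    denom = a + b
    ok = valid & (denom != 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = np.where(ok, (a - b) / np.where(denom == 0.0, 1.0, denom), np.nan)
    return nd, ok


def compute_ndvi(scene: ReflectanceScene) -> IndexRaster:
    """(NIR - red) / (NIR + red); zero-denominator pixels become nodata."""
    nd, ok = _normalized_difference(scene.band("nir"), scene.band("red"), scene.valid)
    return IndexRaster(nd, "NDVI", georef=scene.georef, valid=ok)


def compute_ndwi(scene: ReflectanceScene) -> IndexRaster:
    """(green - NIR) / (green + NIR); zero-denominator pixels become nodata."""
    nd, ok = _normalized_difference(scene.band("green"), scene.band("nir"), scene.valid)
    return IndexRaster(nd, "NDWI", georef=scene.georef, valid=ok)


_DISPATCH = {
    "AVI": compute_avi,
    "FAI": compute_fai,
    "NDVI": lambda scene, profile=None: compute_ndvi(scene),
    "NDWI": lambda scene, profile=None: compute_ndwi(scene),
}


def compute_index(scene: ReflectanceScene, kind: str, profile: SensorProfile | None = None) -> IndexRaster:
    """Compute one index by name (AVI/FAI/NDVI/NDWI)."""
    try:
        fn = _DISPATCH[kind.upper()]
    except KeyError:
        raise ValueError(f"unknown index {kind!r}; choose from {tuple(_DISPATCH)}") from None
    return fn(scene, profile=profile)
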