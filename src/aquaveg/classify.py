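"""Three-step decision-tree classification of lake pixels.

Step 1: AVI separates aquatic vegetation (AV) from non-AV.
Step 2: within AV, NDVI separates floating/emergent vegetation (FEAV,
        high NIR, NDVI above the cut) from submerged vegetation (SAV,
        water-attenuated NIR, NDVI at or below the cut).
Step 3: within non-AV, FAI separates algal bloom (AB, NIR above the
        red-SWIR baseline) from open water (OW).

Every node uses a strict ``>``; a value exactly equal to its threshold
falls to the lower branch, which makes the tree deterministic and
testable at the boundary.

The AVI cut is the one threshold without a natural fixed value: open-water
AVI drifts with atmosphere and water colour, so the usual practice — and the
default of :func:`classify_batch` in auto mode — is per-scene calibration:
extract water with NDWI, take the mean AVI over that water and add
``k_sigma`` standard deviations.  With ``k_sigma = 0`` this is exactly the
water-mean statistic; the default ``k_sigma = 2`` keeps the false-AV rate of
open water near 2.3% under Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .indices import compute_avi, compute_fai, compute_ndvi, compute_ndwi
from .raster import CLASS_CODES, ClassMap, IndexRaster, ReflectanceScene
from .sensors import SensorProfile, get_profile

__all__ = [
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "CalibrationError",
    "extract_water_mask",
    "calibrate_avi_threshold",
    "classify_scene",
    "classify_batch",
    "BatchResult",
]

#: minimum number of water pixels accepted for AVI-threshold calibration
MIN_CALIBRATION_PIXELS = 30


class CalibrationError(RuntimeError):
    """Raised when the water mask is too small to calibrate the AVI cut."""


@dataclass(frozen=True)
class Thresholds:
    """The four decision-tree cuts plus the calibration offset.

    t_avi
        AV vs non-AV cut on AVI.  The fixed default (-0.01) suits scenes
        whose open-water AVI sits near -0.03, but per-scene calibration
        (see :func:`calibrate_avi_threshold`) is preferred whenever enough
        open water is present.
    t_ndvi
        FEAV vs SAV cut on NDVI (default 0.2: emergent canopies are well
        above it, submerged canopies — NIR absorbed by the water column —
        well below).
    t_fai
        AB vs OW cut on FAI (default 0.0: any NIR excess over the
        red-SWIR baseline counts as bloom).
    t_ndwi
        Water-extraction cut on NDWI, used only for calibration
        (default 0.0, the standard open-water cut).
    k_sigma
        Standard-deviation offset added to the water-mean AVI during
        calibration (default 2.0).
    """

    t_avi: float = -0.01
    t_ndvi: float = 0.2
    t_fai: float = 0.0
    t_ndwi: float = 0.0
    k_sigma: float = 2.0

    def __post_init__(self) -> None:
        for name in ("t_avi", "t_ndvi", "t_fai", "t_ndwi", "k_sigma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not -1.0 <= self.t_ndvi <= 1.0:
            raise ValueError("t_ndvi must lie in [-1, 1]")
        if not -1.0 <= self.t_ndwi <= 1.0:
            raise ValueError("t_ndwi must lie in [-1, 1]")

    def to_dict(self) -> dict[str, float]:
        return {
            "t_avi": self.t_avi,
            "t_ndvi": self.t_ndvi,
            "t_fai": self.t_fai,
            "t_ndwi": self.t_ndwi,
            "k_sigma": self.k_sigma,
        }


DEFAULT_THRESHOLDS = Thresholds()


def extract_water_mask(ndwi: IndexRaster, t_ndwi: float = 0.0) -> np.ndarray:
    """Boolean water mask: valid pixels with NDWI strictly above the cut."""
    if ndwi.index_kind != "NDWI":
        raise ValueError(f"expected an NDWI raster, got {ndwi.index_kind}")
    with np.errstate(invalid="ignore"):
        return ndwi.valid & (ndwi.values > t_ndwi)


def calibrate_avi_threshold(
    avi: IndexRaster, water_mask: np.ndarray, k_sigma: float = 2.0
) -> float:
    """AVI cut = mean + ``k_sigma`` * sd of AVI over the water mask.

    With ``k_sigma = 0`` this is the plain water-mean AVI.  Requires at
    least :data:`MIN_CALIBRATION_PIXELS` valid water pixels.
    """
    if avi.index_kind != "AVI":
        raise ValueError(f"expected an AVI raster, got {avi.index_kind}")
    sel = np.asarray(water_mask, dtype=bool) & avi.valid
    n = int(sel.sum())
    if n < MIN_CALIBRATION_PIXELS:
        raise CalibrationError(
            f"only {n} water pixels available for AVI calibration "
            f"(need >= {MIN_CALIBRATION_PIXELS}); lower t_ndwi or supply t_avi"
        )
    vals = avi.values[sel]
    return float(vals.mean() + k_sigma * vals.std(ddof=0))


def classify_scene(
    scene: ReflectanceScene,
    profile: SensorProfile | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scene_id: str | None = None,
    date: str | None = None,
) -> ClassMap:
    """Apply the three-step tree to every valid pixel of ``scene``.

    Nodata pixels (including anything outside a lake mask applied via
    ``scene.with_mask``) stay nodata.  Deterministic: equal inputs give
    equal maps.
    """
    profile = profile if profile is not None else get_profile(scene.sensor_id)
    avi = compute_avi(scene, profile).values
    ndvi = compute_ndvi(scene).values
    fai = compute_fai(scene, profile).values

    labels = np.full(scene.shape, CLASS_CODES["nodata"], dtype=np.uint8)
    v = scene.valid
    with np.errstate(invalid="ignore"):
        is_av = avi > thresholds.t_avi
        is_feav = ndvi > thresholds.t_ndvi
        is_ab = fai > thresholds.t_fai
    labels[v & is_av & is_feav] = CLASS_CODES["FEAV"]
    labels[v & is_av & ~is_feav] = CLASS_CODES["SAV"]
    labels[v & ~is_av & is_ab] = CLASS_CODES["AB"]
    labels[v & ~is_av & ~is_ab] = CLASS_CODES["OW"]

    provenance = {
        "thresholds": thresholds.to_dict(),
        "sensor_id": scene.sensor_id,
    }
    if scene_id is not None:
        provenance["scene_id"] = scene_id
    if date is not None:
        provenance["date"] = date
    return ClassMap(labels, georef=scene.georef, provenance=provenance)


@dataclass
class BatchResult:
    """Per-date classification results plus any per-scene failures."""

    maps: list[tuple[str, ClassMap]]
    failures: list[tuple[str, str]]


def classify_batch(
    scenes: Iterable[tuple[str, ReflectanceScene]],
    profile: SensorProfile | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    auto_avi: bool = False,
) -> BatchResult:
    """Classify a dated scene series.

    With ``auto_avi`` the AVI cut is recalibrated per scene (NDWI water
    extraction, then water-mean + ``k_sigma``*sd) and the calibrated value
    is recorded in each map's provenance.  A scene that fails (e.g. too
    little open water to calibrate) is reported in ``failures`` without
    aborting the rest of the batch.
    """
    maps: list[tuple[str, ClassMap]] = []
    failures: list[tuple[str, str]] = []
    for date, scene in scenes:
        try:
            prof = profile if profile is not None else get_profile(scene.sensor_id)
            th = thresholds
            if auto_avi:
                ndwi = compute_ndwi(scene)
                water = extract_water_mask(ndwi, thresholds.t_ndwi)
                avi = compute_avi(scene, prof)
                t_avi = calibrate_avi_threshold(avi, water, thresholds.k_sigma)
                th = replace(thresholds, t_avi=t_avi)
            cm = classify_scene(scene, prof, th, date=date)
            cm.provenance["auto_avi"] = bool(auto_avi)
            maps.append((date, cm))
        except Exception as exc:  # noqa: BLE001 - per-scene isolation is the contract
            failures.append((date, f"{type(exc).__name__}: {exc}"))
    return BatchResult(maps=maps, failures=failures)
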