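"""In-memory raster containers: reflectance scenes, index planes, class maps.

Conventions used throughout the package
---------------------------------------
* Arrays are row-major ``(row, col)`` with row 0 at the *top* (north) edge.
* Georeferencing is pixel-edge anchored at the top-left corner; point
  sampling and polygon rasterization use pixel *centers*.
* Band order is (blue, green, red, NIR, SWIR1, SWIR2); see
  :data:`aquaveg.sensors.BAND_NAMES`.
* A pixel that is nodata in any band is nodata in all bands; nodata
  propagates unchanged through every index and the classifier.
* Class codes are frozen for interchange: 0 nodata, 1 SAV, 2 FEAV, 3 AB,
  4 OW.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .sensors import BAND_NAMES

__all__ = [
    "CLASS_CODES",
    "CODE_TO_CLASS",
    "CLASS_NAMES",
    "GridGeoref",
    "ReflectanceScene",
    "IndexRaster",
    "ClassMap",
]

CLASS_CODES: dict[str, int] = {"nodata": 0, "SAV": 1, "FEAV": 2, "AB": 3, "OW": 4}
CODE_TO_CLASS: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}
#: the four thematic classes, in confusion-matrix order
CLASS_NAMES = ("FEAV", "SAV", "AB", "OW")


@dataclass(frozen=True)
class GridGeoref:
    """Affine-north-up georeferencing of a raster grid.

    ``(x_origin, y_origin)`` is the outer corner of the top-left pixel;
    ``pixel_size`` is the ground size of one pixel (both axes positive;
    y decreases with increasing row index, as in every north-up raster).
    """

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 30.0
    crs: str = "EPSG:32650"

    def xy_of(self, row: np.ndarray | int, col: np.ndarray | int):
        """Ground coordinates of pixel *centers*."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def rowcol_of(self, x: np.ndarray | float, y: np.ndarray | float):
        """Row/col indices of the pixel whose cell contains ``(x, y)``."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.pixel_size)
        row = np.floor((self.y_origin - np.asarray(y)) / self.pixel_size)
        return row.astype(int), col.astype(int)

    def to_dict(self) -> dict[str, Any]:
        return {
            "x_origin": self.x_origin,
            "y_origin": self.y_origin,
            "pixel_size": self.pixel_size,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GridGeoref":
        return cls(**d)


def _as_valid_mask(valid, shape) -> np.ndarray:
    if valid is None:
        return np.ones(shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != shape:
        raise ValueError(f"valid mask shape {valid.shape} != raster shape {shape}")
    return valid


@dataclass
class ReflectanceScene:
    """A 6-band surface-reflectance scene.

    ``bands`` has shape ``(6, rows, cols)``; values are dimensionless
    reflectance, nominally in [0, 1] (small post-correction negatives are
    tolerated and deliberately not clipped).  ``valid`` is the shared
    nodata footprint: False marks nodata in *all* bands.
    """

    bands: np.ndarray
    sensor_id: str
    georef: GridGeoref = field(default_factory=GridGeoref)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(BAND_NAMES):
            raise ValueError(
                f"bands must have shape (6, rows, cols); got {self.bands.shape}"
            )
        self.valid = _as_valid_mask(self.valid, self.bands.shape[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        """One band plane by name (blue/green/red/nir/swir1/swir2)."""
        try:
            return self.bands[BAND_NAMES.index(name)]
        except ValueError:
            raise KeyError(f"unknown band {name!r}; bands are {BAND_NAMES}") from None

    def with_mask(self, extra_valid: np.ndarray) -> "ReflectanceScene":
        """Scene restricted to ``valid & extra_valid`` (e.g. a lake mask)."""
        return ReflectanceScene(
            bands=self.bands,
            sensor_id=self.sensor_id,
            georef=self.georef,
            valid=self.valid & np.asarray(extra_valid, dtype=bool),
        )

    def crop(self, rows: slice, cols: slice) -> "ReflectanceScene":
        r0 = rows.start or 0
        c0 = cols.start or 0
        g = replace(
            self.georef,
            x_origin=self.georef.x_origin + c0 * self.georef.pixel_size,
            y_origin=self.georef.y_origin - r0 * self.georef.pixel_size,
        )
        return ReflectanceScene(
            bands=self.bands[:, rows, cols],
            sensor_id=self.sensor_id,
            georef=g,
            valid=self.valid[rows, cols],
        )


@dataclass
class IndexRaster:
    """A single per-pixel spectral index plane (AVI, FAI, NDVI or NDWI).

    Invalid pixels hold NaN in ``values`` and False in ``valid``.
    """

    values: np.ndarray
    index_kind: str
    georef: GridGeoref = field(default_factory=GridGeoref)
    valid: np.ndarray | None = None

    _KINDS = ("AVI", "FAI", "NDVI", "NDWI")

    def __post_init__(self) -> None:
        if self.index_kind not in self._KINDS:
            raise ValueError(
                f"index_kind must be one of {self._KINDS}, got {self.index_kind!r}"
            )
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("index raster must be 2-D")
        self.valid = _as_valid_mask(self.valid, self.values.shape)
        self.values = np.where(self.valid, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClassMap:
    """Categorical raster over the lake grid.

    ``labels`` is uint8 with the frozen code table
    (0 nodata, 1 SAV, 2 FEAV, 3 AB, 4 OW).  ``provenance`` records how the
    map was produced (thresholds, scene id, acquisition date).
    """

    labels: np.ndarray
    georef: GridGeoref = field(default_factory=GridGeoref)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("class map must be 2-D")
        bad = set(np.unique(self.labels)) - set(CODE_TO_CLASS)
        if bad:
            raise ValueError(f"unknown class codes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def valid(self) -> np.ndarray:
        return self.labels != CLASS_CODES["nodata"]

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_CODES[name]

    def crop(self, rows: slice, cols: slice) -> "ClassMap":
        r0 = rows.start or 0
        c0 = cols.start or 0
        g = replace(
            self.georef,
            x_origin=self.georef.x_origin + c0 * self.georef.pixel_size,
            y_origin=self.georef.y_origin - r0 * self.georef.pixel_size,
        )
        return ClassMap(self.labels[rows, cols], georef=g, provenance=dict(self.provenance))
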