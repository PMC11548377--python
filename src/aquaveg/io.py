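"""Raster, vector and tabular I/O plus provenance sidecars.

Scenes travel as multiband TIFF (band order blue, green, red, NIR, SWIR1,
SWIR2) with the georeferencing, sensor id, nodata value and band order
stored as a JSON document in the TIFF description tag, so every file the
package writes is re-readable by the package without external GIS
libraries.  Class maps are single-band uint8 TIFF with the frozen code
table (0 nodata, 1 SAV, 2 FEAV, 3 AB, 4 OW).  Lake boundaries are GeoJSON
polygons rasterized by pixel-center membership.  Every written artifact
gets a JSON provenance sidecar (``<path>.meta.json``) recording the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .raster import CLASS_CODES, ClassMap, GridGeoref, IndexRaster, ReflectanceScene
from .sensors import BAND_NAMES

__all__ = [
    "read_scene",
    "write_scene",
    "read_classmap",
    "write_classmap",
    "write_index",
    "rasterize_mask",
    "read_geojson_geometry",
    "write_provenance",
    "config_hash",
]

_NODATA = -9999.0
_FORMAT = "aquaveg-tiff-v1"


def _meta_json(kind: str, georef: GridGeoref, **extra: Any) -> str:
    return json.dumps(
        {"format": _FORMAT, "kind": kind, "georef": georef.to_dict(), **extra}
    )


def _read_meta(path: Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if meta.get("format") != _FORMAT:
            raise ValueError
    except (json.JSONDecodeError, ValueError):
        meta = {}
    return data, meta


def write_scene(scene: ReflectanceScene, path: str | Path) -> Path:
    """Write a 6-band scene as float32 TIFF with embedded georeferencing."""
    path = Path(path)
    data = np.where(scene.valid, scene.bands, _NODATA).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        description=_meta_json(
            "scene",
            scene.georef,
            sensor_id=scene.sensor_id,
            band_order=list(BAND_NAMES),
            nodata=_NODATA,
        ),
    )
    return path


def read_scene(
    path: str | Path,
    band_order: tuple[str, ...] | None = None,
    sensor_id: str | None = None,
    scale: float | None = None,
) -> ReflectanceScene:
    """Read a multiband reflectance TIFF.

    For files written by this package, sensor, band order, nodata and
    georeferencing come from the embedded metadata.  For foreign files,
    pass ``sensor_id`` and (if not blue/green/red/NIR/SWIR1/SWIR2)
    ``band_order``; ``scale`` divides stored integers into reflectance
    (e.g. 10000 for scaled surface-reflectance products).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scene file not found: {path}")
    data, meta = _read_meta(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a multiband raster, got shape {data.shape}")
    # tifffile may return (rows, cols, bands) for interleaved files
    if data.shape[0] not in (len(BAND_NAMES),) and data.shape[-1] == len(BAND_NAMES):
        data = np.moveaxis(data, -1, 0)
    if data.shape[0] < len(BAND_NAMES):
        raise ValueError(
            f"scene needs {len(BAND_NAMES)} bands (blue..swir2), file has "
            f"{data.shape[0]}"
        )
    data = data[: len(BAND_NAMES)].astype(np.float64)

    order = band_order or tuple(meta.get("band_order", BAND_NAMES))
    if set(order) != set(BAND_NAMES):
        raise ValueError(f"band_order must be a permutation of {BAND_NAMES}")
    data = data[[list(order).index(b) for b in BAND_NAMES]]

    nodata = meta.get("nodata", _NODATA)
    valid = ~np.any(data == nodata, axis=0) & ~np.any(np.isnan(data), axis=0)
    data = np.where(valid, data, 0.0)

    if scale:
        data = data / float(scale)
    finite = data[:, valid]
    if finite.size and (finite.min() < -0.5 or finite.max() > 2.0):
        raise ValueError(
            f"reflectance out of plausible range [{finite.min():.3g}, "
            f"{finite.max():.3g}] after scaling; wrong --scale?"
        )

    sid = sensor_id or meta.get("sensor_id")
    if sid is None:
        raise ValueError("sensor_id not in file metadata; pass sensor_id=")
    georef = GridGeoref.from_dict(meta["georef"]) if "georef" in meta else GridGeoref()
    return ReflectanceScene(bands=data, sensor_id=sid, georef=georef, valid=valid)


def write_classmap(classmap: ClassMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        classmap.labels,
        description=_meta_json(
            "classmap", classmap.georef, class_codes=CLASS_CODES,
            provenance=classmap.provenance,
        ),
    )
    return path


def read_classmap(path: str | Path) -> ClassMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"class map not found: {path}")
    data, meta = _read_meta(path)
    if data.ndim != 2:
        raise ValueError(f"class map must be single-band, got shape {data.shape}")
    georef = GridGeoref.from_dict(meta["georef"]) if "georef" in meta else GridGeoref()
    return ClassMap(
        data.astype(np.uint8), georef=georef, provenance=meta.get("provenance", {})
    )


def write_index(index: IndexRaster, path: str | Path) -> Path:
    path = Path(path)
    data = np.where(index.valid, index.values, _NODATA).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        description=_meta_json(
            "index", index.georef, index_kind=index.index_kind, nodata=_NODATA
        ),
    )
    return path


def read_geojson_geometry(path: str | Path):
    """First (multi)polygon geometry from a GeoJSON file, as shapely."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        feats = gj.get("features", [])
        if not feats:
            raise ValueError(f"no features in {path}")
        geoms = [shape(f["geometry"]) for f in feats]
        from shapely.ops import unary_union

        return unary_union(geoms)
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def rasterize_mask(geometry, georef: GridGeoref, shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center-in-polygon boolean mask on the template grid.

    ``geometry`` is a shapely geometry (or a path to a GeoJSON file) in the
    grid's CRS; a raster TIFF path of 0/1 values is also accepted.
    """
    import shapely

    if isinstance(geometry, (str, Path)):
        p = Path(geometry)
        if p.suffix.lower() in (".tif", ".tiff"):
            data, _ = _read_meta(p)
            if data.shape != shape:
                raise ValueError(
                    f"mask raster shape {data.shape} != template shape {shape}"
                )
            return data.astype(bool)
        geometry = read_geojson_geometry(p)

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x, y = georef.xy_of(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(geometry, x, y).reshape(shape)
    if not inside.any():
        raise ValueError(
            "mask geometry does not overlap the raster grid (empty mask)"
        )
    return inside


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config: dict[str, Any],
                     inputs: list[str | Path] | None = None) -> Path:
    """Write ``<path>.meta.json`` recording config, its hash and input digests."""
    from . import __version__

    sidecar = Path(str(path) + ".meta.json")
    record = {
        "software": f"aquaveg {__version__}",
        "config": config,
        "config_hash": config_hash(config),
    }
    if inputs:
        digests = {}
        for p in inputs:
            p = Path(p)
            if p.exists():
                digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        record["input_checksums"] = digests
    sidecar.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return sidecar
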