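"""Raster, vector and tabular I/O for the workflow.

Scenes are multi-band surface-reflectance rasters (values in [0, 1], float32)
on a projected, north-up grid in metres. The coordinate convention is:

* pixel (0, 0) is the top-left pixel;
* the geotransform ``(origin_x, origin_y, pixel_w, pixel_h)`` gives the map
  coordinate of the *outer corner* of pixel (0, 0) and the (positive) pixel
  sizes;
* the map coordinate *of* a pixel refers to its centre:
  ``x = origin_x + (col + 0.5) * pixel_w``, ``y = origin_y - (row + 0.5) * pixel_h``;
* grids are half-open: a point on the right/bottom edge belongs to the next pixel.

Scenes round-trip through GeoTIFF (one raster band per scene band, planar
layout) with the standard georeferencing tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL nodata). Scene metadata travels in a sidecar JSON file.
Field polygons use GeoJSON with coordinates in the scene CRS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    AlignmentError,
    IncompatibleTilesError,
    SchemaError,
    UnsupportedCRSError,
)

#: canonical band-role ordering used for CSV columns and validation
ROLE_ORDER = ("blue", "green", "red", "rededge", "nir1", "nir2", "cyan", "yellow", "pan")
#: roles every usable multispectral scene must provide
MANDATORY_ROLES = ("blue", "green", "red", "nir1")
#: canonical vegetation-index ordering for CSV columns
VI_NAMES = ("ndvi", "gndvi", "evi", "tcari", "simple_ratio", "sarvi", "savi", "msavi2", "ndvi_nir2")
#: the thirteen texture-descriptor column names (order fixed for the texture CSV)
TEXTURE_DESCRIPTORS = (
    "f_asm", "f_contrast", "f_correlation", "f_variance", "f_homogeneity",
    "f_sum_avg", "f_sum_var", "f_sum_entropy", "f_entropy", "f_diff_var",
    "f_diff_entropy", "f_imc", "f_max_corr_coeff",
)

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


def _epsg_code(crs_id: str) -> int:
    try:
        authority, code = crs_id.split(":")
        if authority.upper() != "EPSG":
            raise ValueError
        return int(code)
    except ValueError:
        raise SchemaError(f"crs_id must look like 'EPSG:32630', got {crs_id!r}") from None


def _is_geographic(epsg: int) -> bool:
    # geographic 2-D CRSs live in the 4000-4999 EPSG block (WGS84 = 4326 etc.)
    return 4000 <= epsg <= 4999


@dataclass
class Scene:
    """A multi-band reflectance raster with georeferencing."""

    bands: np.ndarray  # float32, shape (n_bands, height, width)
    band_map: dict[str, int]  # role -> band index
    geotransform: tuple[float, float, float, float]  # (origin_x, origin_y, pixel_w, pixel_h)
    crs_id: str = "EPSG:32630"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        if self.bands.ndim != 3:
            raise SchemaError("Scene.bands must be a 3-D (band, row, col) array")
        n = self.bands.shape[0]
        idx = sorted(self.band_map.values())
        if len(set(idx)) != len(idx) or any(i < 0 or i >= n for i in idx):
            raise SchemaError("band_map indices must be unique and in range")
        for role in self.band_map:
            if role not in ROLE_ORDER:
                raise SchemaError(f"unknown band role {role!r}")
        _, _, pw, ph = self.geotransform
        if pw <= 0 or ph <= 0:
            raise SchemaError("pixel sizes must be positive")

    # -- geometry helpers -------------------------------------------------
    @property
    def height(self) -> int:
        return self.bands.shape[1]

    @property
    def width(self) -> int:
        return self.bands.shape[2]

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster extent."""
        ox, oy, pw, ph = self.geotransform
        return ox, oy - self.height * ph, ox + self.width * pw, oy

    def pixel_to_world(self, rows, cols):
        """Map coordinates of pixel centres."""
        ox, oy, pw, ph = self.geotransform
        return ox + (np.asarray(cols) + 0.5) * pw, oy - (np.asarray(rows) + 0.5) * ph

    def world_to_pixel(self, xs, ys):
        """Fractional (row, col) in pixel-centre coordinates."""
        ox, oy, pw, ph = self.geotransform
        return (oy - np.asarray(ys)) / ph - 0.5, (np.asarray(xs) - ox) / pw - 0.5

    def band(self, role: str) -> np.ndarray:
        if role not in self.band_map:
            raise SchemaError(f"scene has no {role!r} band")
        return self.bands[self.band_map[role]]

    def has_band(self, role: str) -> bool:
        return role in self.band_map

    def valid_mask(self) -> np.ndarray:
        """True where every band holds data (no band equals nodata)."""
        return ~np.any(self.bands == self.nodata, axis=0)

    def roles(self) -> list[str]:
        """Band roles present, in canonical order."""
        return [r for r in ROLE_ORDER if r in self.band_map]

    def copy(self) -> "Scene":
        return replace(self, bands=self.bands.copy(), band_map=dict(self.band_map))


@dataclass
class SceneMetadata:
    """Per-acquisition metadata as delivered alongside each image."""

    scene_id: str
    acquisition_time: datetime
    sun_elevation_deg: float
    sun_azimuth_deg: float
    sat_offnadir_deg: float
    sat_azimuth_deg: float
    cloud_cover_pct: float
    sensor: str = "synthetic"
    band_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.sun_elevation_deg <= 90:
            raise SchemaError("sun_elevation_deg must be in (0, 90]")
        if not 0 <= self.cloud_cover_pct <= 100:
            raise SchemaError("cloud_cover_pct must be in [0, 100]")
        if not 0 <= self.sat_offnadir_deg < 90:
            raise SchemaError("sat_offnadir_deg must be in [0, 90)")

    def to_json(self, path: str | Path) -> None:
        d = {
            "scene_id": self.scene_id,
            "acquisition_time": self.acquisition_time.isoformat(),
            "sun_elevation_deg": self.sun_elevation_deg,
            "sun_azimuth_deg": self.sun_azimuth_deg,
            "sat_offnadir_deg": self.sat_offnadir_deg,
            "sat_azimuth_deg": self.sat_azimuth_deg,
            "cloud_cover_pct": self.cloud_cover_pct,
            "sensor": self.sensor,
            "band_roles": list(self.band_roles),
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneMetadata":
        d = json.loads(Path(path).read_text())
        d["acquisition_time"] = datetime.fromisoformat(d["acquisition_time"])
        return cls(**d)


@dataclass
class FieldPolygon:
    """A farm parcel with a crop label; ring vertices in map metres (scene CRS)."""

    field_id: str
    crop: str
    ring: list[tuple[float, float]]

    def __post_init__(self) -> None:
        ring = [tuple(map(float, v)) for v in self.ring]
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        if len(set(ring[:-1])) < 3:
            raise SchemaError(f"field {self.field_id}: polygon needs >= 3 distinct vertices")
        self.ring = ring

    def shapely(self):
        from shapely.geometry import Polygon

        p = Polygon(self.ring)
        if not p.is_valid or p.area <= 0:
            raise SchemaError(f"field {self.field_id}: invalid or zero-area polygon")
        return p


# ---------------------------------------------------------------------------
# Scene GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, path: str | Path) -> None:
    """Write a Scene as a multi-band float32 GeoTIFF."""
    ox, oy, pw, ph = scene.geotransform
    epsg = _epsg_code(scene.crs_id)
    model_type = 2 if _is_geographic(epsg) else 1
    cs_key = 2048 if model_type == 2 else 3072
    geokeys = (1, 1, 0, 3, 1024, 0, 1, model_type, 1025, 0, 1, 1, cs_key, 0, 1, epsg)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(pw), float(ph), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(scene.nodata))),
    ]
    tifffile.imwrite(
        str(path),
        scene.bands,
        photometric="minisblack",
        planarconfig="separate",
        extratags=extratags,
        metadata=None,
    )


def read_scene(path: str | Path, metadata_path: str | Path) -> tuple[Scene, SceneMetadata]:
    """Read a GeoTIFF scene plus its sidecar metadata JSON.

    Band roles are resolved from the metadata's ``band_roles`` list (index
    order). A geographic CRS or a missing mandatory role is an error.
    """
    meta = SceneMetadata.from_json(metadata_path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        page = tf.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise SchemaError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        ox, oy = tp[3] - tp[0] * sx, tp[4] + tp[1] * sy
        epsg = 0
        model_type = 1
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            for k in range(4, len(keys), 4):
                key_id, _, _, val = keys[k : k + 4]
                if key_id == 1024:
                    model_type = val
                elif key_id in (2048, 3072):
                    epsg = val
        if model_type == 2 or _is_geographic(epsg):
            raise UnsupportedCRSError(
                f"{path}: geographic CRS (EPSG:{epsg}); a projected CRS in metres is required"
            )
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if arr.ndim == 2:
        arr = arr[None]
    roles = meta.band_roles
    if len(roles) != arr.shape[0]:
        raise SchemaError(
            f"{path}: metadata lists {len(roles)} band roles but file has {arr.shape[0]} bands"
        )
    band_map = {role: i for i, role in enumerate(roles)}
    for role in MANDATORY_ROLES:
        if role not in band_map:
            raise SchemaError(f"{path}: mandatory band role {role!r} missing")
    scene = Scene(
        bands=arr.astype(np.float32),
        band_map=band_map,
        geotransform=(float(ox), float(oy), float(sx), float(sy)),
        crs_id=f"EPSG:{epsg}" if epsg else "EPSG:0",
        nodata=nodata,
    )
    return scene, meta


def write_mask_raster(grid: np.ndarray, geotransform, crs_id: str, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit (0/1) single-band GeoTIFF."""
    ox, oy, pw, ph = geotransform
    epsg = _epsg_code(crs_id)
    geokeys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, epsg)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(pw), float(ph), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
    ]
    tifffile.imwrite(
        str(path),
        grid.astype(np.uint8),
        photometric="minisblack",
        extratags=extratags,
        metadata=None,
    )


def read_mask_raster(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask GeoTIFF back to a boolean grid."""
    return tifffile.imread(str(path)).astype(bool)


def read_mask_raster_with_transform(
    path: str | Path,
) -> tuple[np.ndarray, tuple[float, float, float, float], str]:
    """Read a mask grid plus its (origin_x, origin_y, pixel_w, pixel_h) and CRS id."""
    with tifffile.TiffFile(str(path)) as tf:
        grid = tf.asarray().astype(bool)
        tags = tf.pages[0].tags
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        epsg = 0
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            for k in range(4, len(keys), 4):
                if keys[k] in (2048, 3072):
                    epsg = keys[k + 3]
    return grid, (float(tp[3]), float(tp[4]), float(sx), float(sy)), f"EPSG:{epsg}"


# ---------------------------------------------------------------------------
# Tile mosaicking
# ---------------------------------------------------------------------------

def stitch_tiles(tiles: Sequence[Scene]) -> Scene:
    """Mosaic co-gridded tiles into one scene (union bounding box).

    Every output pixel takes the value of the *first* tile (input order) whose
    extent covers it; pixels covered by no tile are nodata. Tiles must share
    CRS, band count and pixel size, and their origins must differ by integer
    pixel multiples.
    """
    if not tiles:
        raise IncompatibleTilesError("no tiles to stitch")
    ref = tiles[0]
    _, _, pw, ph = ref.geotransform
    for t in tiles[1:]:
        if t.crs_id != ref.crs_id:
            raise IncompatibleTilesError(f"CRS mismatch: {t.crs_id} vs {ref.crs_id}")
        if t.n_bands != ref.n_bands or t.band_map != ref.band_map:
            raise IncompatibleTilesError("band count/roles differ between tiles")
        if not (math.isclose(t.geotransform[2], pw) and math.isclose(t.geotransform[3], ph)):
            raise IncompatibleTilesError("pixel size differs between tiles")
        dx = (t.geotransform[0] - ref.geotransform[0]) / pw
        dy = (t.geotransform[1] - ref.geotransform[1]) / ph
        if abs(dx - round(dx)) > 1e-6 or abs(dy - round(dy)) > 1e-6:
            raise AlignmentError("tile grids are not co-aligned on a common lattice")

    ox = min(t.geotransform[0] for t in tiles)
    oy = max(t.geotransform[1] for t in tiles)
    xmax = max(t.geotransform[0] + t.width * pw for t in tiles)
    ymin = min(t.geotransform[1] - t.height * ph for t in tiles)
    width = round((xmax - ox) / pw)
    height = round((oy - ymin) / ph)

    out = np.full((ref.n_bands, height, width), ref.nodata, dtype=np.float32)
    covered = np.zeros((height, width), dtype=bool)
    for t in tiles:
        r0 = round((oy - t.geotransform[1]) / ph)
        c0 = round((t.geotransform[0] - ox) / pw)
        sl = (slice(r0, r0 + t.height), slice(c0, c0 + t.width))
        fill = ~covered[sl]
        out[:, sl[0], sl[1]] = np.where(fill[None], t.bands, out[:, sl[0], sl[1]])
        covered[sl] = True
    return Scene(out, dict(ref.band_map), (ox, oy, pw, ph), ref.crs_id, ref.nodata)


# ---------------------------------------------------------------------------
# Field polygons (GeoJSON)
# ---------------------------------------------------------------------------

def write_fields(fields: Iterable[FieldPolygon], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"field_id": f.field_id, "crop": f.crop},
            "geometry": {"type": "Polygon", "coordinates": [[list(v) for v in f.ring]]},
        }
        for f in fields
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=2))


def read_fields(path: str | Path) -> list[FieldPolygon]:
    gj = json.loads(Path(path).read_text())
    out = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise SchemaError(f"field geometry must be Polygon, got {geom['type']}")
        ring = [tuple(v) for v in geom["coordinates"][0]]
        out.append(
            FieldPolygon(
                field_id=str(props.get("field_id", f"field_{len(out)}")),
                crop=str(props.get("crop", "unknown")),
                ring=ring,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Signature CSVs
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # >= 9 significant digits


def _role_pairs(roles: Sequence[str]) -> list[tuple[str, str]]:
    return [(roles[i], roles[j]) for i in range(len(roles)) for j in range(i + 1, len(roles))]


def spectral_csv_columns(roles: Sequence[str]) -> list[str]:
    cols = ["scene_id", "field_id", "crop", "date", "n_total", "n_used"]
    for r in roles:
        cols += [f"{r}_mean", f"{r}_var", f"{r}_skew"]
    cols += [f"corr_{i}_{j}" for i, j in _role_pairs(roles)]
    cols += [f"cov_{i}_{j}" for i, j in _role_pairs(roles)]
    for name in VI_NAMES:
        cols += [f"{name}_mean", f"{name}_sd"]
    return cols


def write_spectral_csv(records: Sequence, path: str | Path) -> None:
    """Write per-field spectral records for one image to CSV.

    Undefined statistics (fields with no usable pixels, constant bands, absent
    sensor bands) are rendered as empty cells, never as 0 or NaN text.
    """
    _check_single_scene(records)
    roles = list(records[0].band_roles) if records else list(MANDATORY_ROLES)
    cols = spectral_csv_columns(roles)
    rows = []
    for rec in records:
        row: dict = {
            "scene_id": rec.scene_id,
            "field_id": rec.field_id,
            "crop": rec.crop,
            "date": rec.date,
            "n_total": rec.n_total,
            "n_used": rec.n_used,
        }
        for r in roles:
            m, v, s = rec.band_stats.get(r, (np.nan, np.nan, np.nan))
            row[f"{r}_mean"], row[f"{r}_var"], row[f"{r}_skew"] = m, v, s
        for i, j in _role_pairs(roles):
            row[f"corr_{i}_{j}"] = rec.corr.get((i, j), np.nan)
            row[f"cov_{i}_{j}"] = rec.cov.get((i, j), np.nan)
        for name in VI_NAMES:
            m, s = rec.vi.get(name, (np.nan, np.nan))
            row[f"{name}_mean"], row[f"{name}_sd"] = m, s
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


TEXTURE_CSV_COLUMNS = (
    ["scene_id", "field_id", "grey_levels", "angle_deg"]
    + list(TEXTURE_DESCRIPTORS)
    + ["f_imc2_aux"]
)


def write_texture_csv(records: Sequence, path: str | Path) -> None:
    """Write per-field GLCM texture records for one image to CSV."""
    _check_single_scene(records)
    rows = []
    for rec in records:
        row = {
            "scene_id": rec.scene_id,
            "field_id": rec.field_id,
            "grey_levels": rec.grey_levels,
            "angle_deg": rec.angle_deg,
        }
        for name in TEXTURE_DESCRIPTORS:
            row[name] = rec.descriptors.get(name, np.nan)
        row["f_imc2_aux"] = rec.descriptors.get("f_imc2_aux", np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=TEXTURE_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


def _check_single_scene(records: Sequence) -> None:
    ids = {rec.scene_id for rec in records}
    if len(ids) > 1:
        raise SchemaError(f"records mix scene_ids: {sorted(ids)}; one CSV per image")
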