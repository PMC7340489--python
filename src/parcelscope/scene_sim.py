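"""Synthetic multispectral scene generator with known ground truth.

Real very-high-resolution imagery (WorldView, GeoEye, QuickBird, RapidEye) is
proprietary, so the rest of the workflow is exercised on simulated scenes that
reproduce the structures the algorithms key on:

* isolated tree crowns rendered as additive isotropic 2-D Gaussian bumps
  ("bell-shaped" intensity surfaces) on the NIR and green bands;
* homogeneous rectangular crop parcels with additive Gaussian sensor noise;
* cloud patches grown from random seeds whose blue-band reflectance is set
  strictly above the brightest background pixel, so the brightest-blue-pixel
  premise of the cloud-masking step holds by construction;
* a known inter-scene translation for registration experiments.

Everything injected is recorded in a :class:`GroundTruth` object, and identical
configuration + seed yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .raster_io import FieldPolygon, Scene, SceneMetadata

#: background (dry soil) reflectance per band role; soil NDVI ~0.14
BACKGROUND_REFLECTANCE = {
    "blue": 0.06,
    "green": 0.10,
    "red": 0.18,
    "rededge": 0.21,
    "nir1": 0.24,
    "nir2": 0.25,
}

#: default crop-canopy reflectance per band role; canopy NDVI ~0.65
DEFAULT_FIELD_REFLECTANCE = {
    "blue": 0.05,
    "green": 0.11,
    "red": 0.08,
    "rededge": 0.22,
    "nir1": 0.38,
    "nir2": 0.40,
}

#: bands a crown bump is added to (crowns are bright in NIR and green)
CROWN_BANDS = ("green", "nir1", "nir2")

DEFAULT_BAND_ROLES = ("blue", "green", "red", "rededge", "nir1", "nir2")

CROP_LABELS = ("maize", "peanut", "cotton", "soybean", "millet", "sorghum")


@dataclass
class SimConfig:
    """Parameters of one synthetic acquisition.

    Defaults describe a 512 x 512 m savanna tile at 2 m ground sampling
    distance with 20 isolated trees (crown scale 4-8 m, i.e. 2-4 px), five
    crop parcels, 1% reflectance sensor noise and no clouds.
    """

    width_px: int = 256
    height_px: int = 256
    gsd_m: float = 2.0
    origin_xy: tuple[float, float] = (500000.0, 1400000.0)
    n_trees: int = 20
    crown_sigma_range_m: tuple[float, float] = (4.0, 8.0)
    crown_amplitude: float = 0.25
    n_fields: int = 5
    field_reflectance: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_REFLECTANCE)
    )
    noise_sd: float = 0.01
    cloud_fraction: float = 0.0
    shift_xy_m: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    band_roles: tuple[str, ...] = DEFAULT_BAND_ROLES
    crs_id: str = "EPSG:32630"
    #: minimum crown separation as a multiple of the largest crown sigma
    min_separation_sigmas: float = 6.0
    canopy_height_m: float = 10.0

    def validate(self) -> None:
        if self.width_px < 32:
            raise ConfigError("width_px must be >= 32")
        if self.height_px < 32:
            raise ConfigError("height_px must be >= 32")
        if self.gsd_m <= 0:
            raise ConfigError("gsd_m must be positive")
        if not 0 <= self.cloud_fraction <= 1:
            raise ConfigError("cloud_fraction must be in [0, 1]")
        lo, hi = self.crown_sigma_range_m
        if not 0 < lo <= hi:
            raise ConfigError("crown_sigma_range_m must satisfy 0 < min <= max")
        if not 0 <= self.crown_amplitude <= 1:
            raise ConfigError("crown_amplitude must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_trees < 0:
            raise ConfigError("n_trees must be >= 0")
        if self.n_fields < 0:
            raise ConfigError("n_fields must be >= 0")
        for role, val in self.field_reflectance.items():
            if not 0 <= val <= 1:
                raise ConfigError(f"field_reflectance[{role!r}] must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything injected into a synthetic scene."""

    crowns: list[tuple[float, float, float, float]]  # (x_m, y_m, sigma_m, height_m)
    cloud_pixels: set[tuple[int, int]]  # (row, col)
    true_shift_xy_m: tuple[float, float]
    field_polygons: list[FieldPolygon]

    def to_json(self, path: str | Path) -> None:
        d = {
            "crowns": [list(c) for c in self.crowns],
            "cloud_pixels": sorted(self.cloud_pixels),
            "true_shift_xy_m": list(self.true_shift_xy_m),
            "field_polygons": [
                {"field_id": f.field_id, "crop": f.crop, "ring": f.ring}
                for f in self.field_polygons
            ],
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            crowns=[tuple(c) for c in d["crowns"]],
            cloud_pixels={tuple(p) for p in d["cloud_pixels"]},
            true_shift_xy_m=tuple(d["true_shift_xy_m"]),
            field_polygons=[
                FieldPolygon(f["field_id"], f["crop"], [tuple(v) for v in f["ring"]])
                for f in d["field_polygons"]
            ],
        )


def _place_fields(cfg: SimConfig, rng: np.random.Generator) -> list[FieldPolygon]:
    """Non-overlapping axis-aligned rectangular parcels, 30-60 m a side."""
    ox, oy = cfg.origin_xy
    w_m, h_m = cfg.width_px * cfg.gsd_m, cfg.height_px * cfg.gsd_m
    placed: list[tuple[float, float, float, float]] = []  # (x0, y0, x1, y1), y0 < y1
    fields: list[FieldPolygon] = []
    attempts = 0
    while len(fields) < cfg.n_fields and attempts < 400 * max(cfg.n_fields, 1):
        attempts += 1
        fw = rng.uniform(30.0, 60.0)
        fh = rng.uniform(30.0, 60.0)
        x0 = ox + rng.uniform(0.05 * w_m, 0.95 * w_m - fw)
        y1 = oy - rng.uniform(0.05 * h_m, 0.95 * h_m - fh)  # top edge
        y0 = y1 - fh
        box = (x0 - 10, y0 - 10, x0 + fw + 10, y1 + 10)
        if any(not (box[2] < b[0] or box[0] > b[2] or box[3] < b[1] or box[1] > b[3]) for b in placed):
            continue
        placed.append((x0, y0, x0 + fw, y1))
        i = len(fields)
        fields.append(
            FieldPolygon(
                field_id=f"F{i:03d}",
                crop=CROP_LABELS[i % len(CROP_LABELS)],
                ring=[(x0, y0), (x0 + fw, y0), (x0 + fw, y1), (x0, y1), (x0, y0)],
            )
        )
    if len(fields) < cfg.n_fields:
        raise ConfigError("n_fields: could not place that many non-overlapping parcels")
    return fields


def _place_crowns(
    cfg: SimConfig, rng: np.random.Generator, fields: list[FieldPolygon]
) -> list[tuple[float, float, float, float]]:
    """Crown centres with a minimum mutual separation, clear of parcels and edges."""
    ox, oy = cfg.origin_xy
    w_m, h_m = cfg.width_px * cfg.gsd_m, cfg.height_px * cfg.gsd_m
    lo, hi = cfg.crown_sigma_range_m
    min_sep = cfg.min_separation_sigmas * hi
    margin = 4.0 * hi
    boxes = []
    for f in fields:
        xs = [v[0] for v in f.ring]
        ys = [v[1] for v in f.ring]
        boxes.append((min(xs) - 2 * hi, min(ys) - 2 * hi, max(xs) + 2 * hi, max(ys) + 2 * hi))
    crowns: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(crowns) < cfg.n_trees and attempts < 2000 * max(cfg.n_trees, 1):
        attempts += 1
        x = ox + rng.uniform(margin, w_m - margin)
        y = oy - rng.uniform(margin, h_m - margin)
        if any(b[0] <= x <= b[2] and b[1] <= y <= b[3] for b in boxes):
            continue
        if any((x - c[0]) ** 2 + (y - c[1]) ** 2 < min_sep**2 for c in crowns):
            continue
        sigma = rng.uniform(lo, hi)
        height = rng.uniform(6.0, 14.0)
        crowns.append((x, y, sigma, height))
    if len(crowns) < cfg.n_trees:
        raise ConfigError("n_trees: could not place that many separated crowns; enlarge the scene")
    return crowns


def _grow_cloud_pixels(
    k: int, height: int, width: int, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Region-grow k pixels from random seeds (roughly one patch per 500 px)."""
    if k <= 0:
        return set()
    n_seeds = max(1, k // 500)
    chosen: set[tuple[int, int]] = set()
    frontier: list[tuple[int, int]] = []
    for _ in range(n_seeds):
        p = (int(rng.integers(height)), int(rng.integers(width)))
        if p not in chosen:
            chosen.add(p)
            frontier.append(p)
    while len(chosen) < k:
        if not frontier:  # disconnected restart
            p = (int(rng.integers(height)), int(rng.integers(width)))
            if p in chosen:
                continue
            chosen.add(p)
            frontier.append(p)
            continue
        i = int(rng.integers(len(frontier)))
        r, c = frontier[i]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < height and 0 <= c + dc < width and (r + dr, c + dc) not in chosen
        ]
        if not nbrs:
            frontier.pop(i)
            continue
        p = nbrs[int(rng.integers(len(nbrs)))]
        chosen.add(p)
        frontier.append(p)
        if len(chosen) >= k:
            break
    return chosen


def _paint_clouds(
    bands: np.ndarray,
    roles: list[str],
    cloud_pixels: set[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Set cloud-pixel reflectances: blue strictly above every background value."""
    if not cloud_pixels:
        return
    ci = tuple(np.array(sorted(cloud_pixels)).T)
    bands[roles.index("blue")][ci] = 0.85 + 0.10 * rng.random(len(cloud_pixels))
    for role in ("green", "red", "rededge"):
        if role in roles:
            bands[roles.index(role)][ci] = np.minimum(1.0, bands[roles.index(role)][ci] + 0.6)
    for role in ("nir1", "nir2"):
        if role in roles:
            bands[roles.index(role)][ci] = np.minimum(1.0, bands[roles.index(role)][ci] + 0.4)


def add_clouds(scene: Scene, cloud_fraction: float, seed: int) -> set[tuple[int, int]]:
    """Inject grown cloud patches into a scene in place; returns the pixel set.

    Used by the site simulator so that each acquisition gets its own cloud
    field — clouds, unlike the landscape, are independent between dates.
    """
    if not 0 <= cloud_fraction <= 1:
        raise ConfigError("cloud_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = scene.height, scene.width
    k = round(cloud_fraction * h * w)
    pixels = _grow_cloud_pixels(k, h, w, rng)
    roles = [None] * scene.n_bands
    for role, idx in scene.band_map.items():
        roles[idx] = role
    _paint_clouds(scene.bands, roles, pixels, rng)
    return pixels


def render_bands(
    cfg: SimConfig,
    crowns: list[tuple[float, float, float, float]],
    fields: list[FieldPolygon],
    rng: np.random.Generator,
    content_shift_xy_m: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Render background, parcels and crown bumps plus sensor noise.

    Crown tuples are taken at their (apparent) positions as given; field
    rectangles are translated by ``content_shift_xy_m`` (a georeferencing
    error moves everything on the ground together; crowns get their parallax
    added by the caller on top of the same shift).
    """
    roles = list(cfg.band_roles)
    h, w = cfg.height_px, cfg.width_px
    ox, oy = cfg.origin_xy
    gsd = cfg.gsd_m
    sx, sy = content_shift_xy_m

    bands = np.empty((len(roles), h, w), dtype=np.float64)
    for bi, role in enumerate(roles):
        bands[bi] = BACKGROUND_REFLECTANCE.get(role, 0.15)

    xs = ox + (np.arange(w) + 0.5) * gsd
    ys = oy - (np.arange(h) + 0.5) * gsd
    for f in fields:
        fx = [v[0] + sx for v in f.ring]
        fy = [v[1] + sy for v in f.ring]
        cin = (xs >= min(fx)) & (xs < max(fx))
        rin = (ys > min(fy)) & (ys <= max(fy))
        sel = np.ix_(rin, cin)
        for bi, role in enumerate(roles):
            bands[bi][sel] = cfg.field_reflectance.get(role, BACKGROUND_REFLECTANCE.get(role, 0.15))

    for x, y, sigma_m, _height in crowns:
        s_px = sigma_m / gsd
        cc = (x - ox) / gsd - 0.5  # fractional centre col
        cr = (oy - y) / gsd - 0.5
        r0, r1 = max(0, int(cr - 4 * s_px)), min(h, int(cr + 4 * s_px) + 2)
        c0, c1 = max(0, int(cc - 4 * s_px)), min(w, int(cc + 4 * s_px) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc_grid = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        bump = cfg.crown_amplitude * np.exp(
            -((rr - cr) ** 2 + (cc_grid - cc) ** 2) / (2 * s_px**2)
        )
        for role in CROWN_BANDS:
            if role in roles:
                bands[roles.index(role)][r0:r1, c0:c1] += bump

    if cfg.noise_sd > 0:
        bands += rng.normal(0.0, cfg.noise_sd, size=bands.shape)
    np.clip(bands, 0.0, 1.0, out=bands)
    return bands


def make_scene(cfg: SimConfig) -> tuple[Scene, SceneMetadata, GroundTruth]:
    """Render one synthetic acquisition and its ground truth.

    The number of injected cloud pixels is exactly
    ``round(cloud_fraction * width_px * height_px)``, and cloud pixels are
    strictly the brightest blue-band pixels of the scene.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    roles = list(cfg.band_roles)
    h, w = cfg.height_px, cfg.width_px
    ox, oy = cfg.origin_xy
    gsd = cfg.gsd_m

    fields = _place_fields(cfg, rng)
    crowns = _place_crowns(cfg, rng, fields)
    bands = render_bands(cfg, crowns, fields, rng)

    k = round(cfg.cloud_fraction * h * w)
    cloud_pixels = _grow_cloud_pixels(k, h, w, rng)
    _paint_clouds(bands, roles, cloud_pixels, rng)

    scene = Scene(
        bands=bands.astype(np.float32),
        band_map={r: i for i, r in enumerate(roles)},
        geotransform=(float(ox), float(oy), gsd, gsd),
        crs_id=cfg.crs_id,
    )
    meta = SceneMetadata(
        scene_id=f"SYN{cfg.seed:04d}",
        acquisition_time=datetime(2015, 5, 18, 10, 46, tzinfo=timezone.utc)
        + timedelta(days=int(cfg.seed) % 365),
        sun_elevation_deg=40.0 + (cfg.seed * 7) % 40,
        sun_azimuth_deg=120.0,
        sat_offnadir_deg=0.0,
        sat_azimuth_deg=90.0,
        cloud_cover_pct=100.0 * cfg.cloud_fraction,
        sensor="synthetic",
        band_roles=roles,
    )
    truth = GroundTruth(
        crowns=crowns,
        cloud_pixels=cloud_pixels,
        true_shift_xy_m=tuple(cfg.shift_xy_m),
        field_polygons=fields,
    )
    return scene, meta, truth


def simulate_site(
    out_dir: str | Path,
    n_scenes: int = 3,
    cfg: SimConfig | None = None,
    max_shift_px: float = 5.0,
) -> list[str]:
    """Write a multi-acquisition synthetic site to a directory.

    One landscape (parcels + trees) is imaged ``n_scenes`` times. Scene 0 is
    the nadir, lowest-sun acquisition (hence the master under the
    longest-shadow rule). Each later acquisition gets (a) a known
    integer-pixel georeferencing shift that moves all ground content together,
    (b) crown parallax -- each crown top additionally displaced by its own
    height * tan(off-nadir) along the satellite azimuth, (c) fresh sensor
    noise, and (d) its own cloud field (clouds, unlike the landscape, are
    independent between dates). The directory receives ``<id>.tif`` +
    ``<id>.json`` per scene, the true parcel polygons as ``fields.geojson``
    and per-scene ground truth as ``truth_<id>.json``. Returns the scene ids.
    """
    import math

    from . import raster_io

    cfg = cfg or SimConfig()
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    fields = _place_fields(cfg, rng)
    crowns = _place_crowns(cfg, rng, fields)
    shift_rng = np.random.default_rng(cfg.seed + 1_000_003)
    base_time = datetime(2015, 5, 18, 10, 46, tzinfo=timezone.utc)

    ids: list[str] = []
    for i in range(n_scenes):
        sid = f"SYN{cfg.seed:04d}_{i:02d}"
        if i == 0:
            shift = (0.0, 0.0)
            sun_elev, offnadir, sat_az = 25.0, 0.0, 90.0
        else:
            shift_px = shift_rng.integers(-int(max_shift_px), int(max_shift_px) + 1, size=2)
            shift = (float(shift_px[0]) * cfg.gsd_m, float(shift_px[1]) * cfg.gsd_m)
            sun_elev = 40.0 + 10.0 * i
            offnadir, sat_az = float(5 * i), 90.0
        tan_t = math.tan(math.radians(offnadir))
        az = math.radians(sat_az)
        apparent = [
            (
                x + shift[0] + h_tree * tan_t * math.sin(az),
                y + shift[1] + h_tree * tan_t * math.cos(az),
                s,
                h_tree,
            )
            for x, y, s, h_tree in crowns
        ]
        scene_rng = np.random.default_rng(cfg.seed + 31 * (i + 1))
        bands = render_bands(cfg, apparent, fields, scene_rng, content_shift_xy_m=shift)
        scene = Scene(
            bands=bands.astype(np.float32),
            band_map={r: bi for bi, r in enumerate(cfg.band_roles)},
            geotransform=(float(cfg.origin_xy[0]), float(cfg.origin_xy[1]), cfg.gsd_m, cfg.gsd_m),
            crs_id=cfg.crs_id,
        )
        cloud_pixels = add_clouds(scene, cfg.cloud_fraction, cfg.seed + 7919 * (i + 1))
        truth = GroundTruth(
            crowns=apparent,
            cloud_pixels=cloud_pixels,
            true_shift_xy_m=shift,
            field_polygons=fields,
        )
        meta = SceneMetadata(
            scene_id=sid,
            acquisition_time=base_time + timedelta(days=16 * i),
            sun_elevation_deg=sun_elev,
            sun_azimuth_deg=120.0,
            sat_offnadir_deg=offnadir,
            sat_azimuth_deg=sat_az,
            cloud_cover_pct=100.0 * cfg.cloud_fraction,
            sensor="synthetic",
            band_roles=list(cfg.band_roles),
        )
        raster_io.write_scene(scene, out / f"{sid}.tif")
        meta.to_json(out / f"{sid}.json")
        truth.to_json(out / f"truth_{sid}.json")
        ids.append(sid)
    raster_io.write_fields(fields, out / "fields.geojson")
    return ids


def make_shifted_copy(scene: Scene, shift_xy_m: tuple[float, float], resampling: str = "nearest") -> Scene:
    """Translate scene *content* by ``shift_xy_m`` on an unchanged grid.

    A ground feature at map position ``p`` in the input appears at
    ``p + shift`` in the output. Integer-pixel shifts with nearest resampling
    are lossless in the interior; uncovered margins become nodata.
    """
    sx, sy = shift_xy_m
    _, _, pw, ph = scene.geotransform
    if abs(sx) >= scene.width * pw or abs(sy) >= scene.height * ph:
        raise ConfigError("shift_xy_m exceeds the scene extent")
    if resampling not in ("nearest", "bilinear"):
        raise ConfigError(f"resampling must be nearest|bilinear, got {resampling!r}")
    order = 0 if resampling == "nearest" else 1
    rows, cols = np.meshgrid(np.arange(scene.height), np.arange(scene.width), indexing="ij")
    # out(p) = in(p - shift); map x offset -> col, map y offset -> -row
    src_r = rows + sy / ph
    src_c = cols - sx / pw
    out = np.empty_like(scene.bands)
    inside = (
        (src_r >= 0) & (src_r <= scene.height - 1) & (src_c >= 0) & (src_c <= scene.width - 1)
    )
    for bi in range(scene.n_bands):
        out[bi] = ndimage.map_coordinates(
            scene.bands[bi],
            [src_r, src_c],
            order=order,
            mode="constant",
            cval=scene.nodata,
        )
        out[bi][~inside] = scene.nodata
    return Scene(out, dict(scene.band_map), scene.geotransform, scene.crs_id, scene.nodata)
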