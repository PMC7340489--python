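"""Cloud and tree masks.

Cloud masking assumes that, in low-latitude agricultural landscapes without
snow or other highly reflective cover, cloudy pixels are the brightest pixels
of a short-wavelength band. The scene's own metadata states the percentage of
cloudy pixels, so the detection reduces to a histogram threshold on the blue
band at that percentage. Ties at the threshold are excluded (strict
inequality), so the masked fraction never exceeds the metadata percentage.

Tree masking reuses the crown blobs found during co-registration on the master
scene: a pixel is masked when it lies within a configurable multiple of a
crown's characteristic scale AND its NDVI exceeds a deliberately lowered
vegetation threshold (false negatives on farm fields are costlier than false
positives on the crown fringe). For the other scenes of a site, the master
mask is translated by the parallax displacement canopy_height * tan(off-nadir)
along the satellite azimuth, rounded to whole pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coregister import Blob
from .errors import ConfigError, SchemaError
from .raster_io import Scene, SceneMetadata


@dataclass
class Mask:
    """A boolean raster aligned to a scene; True = masked out."""

    grid: np.ndarray
    kind: str  # "cloud" | "tree" | "combined"
    source_scene_id: str
    pixel_size_m: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise SchemaError("Mask.grid must be 2-D")


@dataclass
class TreeMaskConfig:
    ndvi_threshold: float = 0.2
    crown_radius_factor: float = 2.0
    canopy_height_m: float = 10.0

    def validate(self) -> None:
        if not -1.0 <= self.ndvi_threshold <= 1.0:
            raise ConfigError("ndvi_threshold must be in [-1, 1]")
        if self.crown_radius_factor <= 0:
            raise ConfigError("crown_radius_factor must be positive")


def cloud_mask(scene: Scene, metadata: SceneMetadata) -> Mask:
    """Brightest-blue-pixel cloud mask at the metadata cloud percentage.

    Masked pixels are exactly those whose blue reflectance is strictly greater
    than the (1 - p/100) order-statistic quantile of the valid blue pixels.
    Nodata pixels are never masked.
    """
    blue = scene.band("blue")
    p = metadata.cloud_cover_pct
    valid = blue != scene.nodata
    grid = np.zeros(blue.shape, dtype=bool)
    if p > 0 and valid.any():
        thr = np.quantile(blue[valid], 1.0 - p / 100.0, method="lower")
        grid = (blue > thr) & valid
    _, _, pw, ph = scene.geotransform
    return Mask(grid, "cloud", metadata.scene_id, (pw, ph))


def tree_mask_master(
    master: Scene, blobs, cfg: TreeMaskConfig | None = None, scene_id: str = "master"
) -> Mask:
    """Crown mask on the master scene: within crown footprint AND vegetated.

    The crown footprint is a disc of radius crown_radius_factor * sigma around
    each blob centroid (pixel-centre rule); the NDVI gate keeps only pixels
    with (NIR - red)/(NIR + red) strictly above the lowered threshold.
    """
    cfg = cfg or TreeMaskConfig()
    cfg.validate()
    red = master.band("red").astype(np.float64)
    nir = master.band("nir1").astype(np.float64)
    h, w = red.shape
    grid = np.zeros((h, w), dtype=bool)
    ox, oy, pw, ph = master.geotransform
    for b in blobs:
        radius = cfg.crown_radius_factor * b.sigma_m
        cr = (oy - b.y_m) / ph - 0.5
        cc = (b.x_m - ox) / pw - 0.5
        r0 = max(0, int(math.floor(cr - radius / ph)))
        r1 = min(h, int(math.ceil(cr + radius / ph)) + 1)
        c0 = max(0, int(math.floor(cc - radius / pw)))
        c1 = min(w, int(math.ceil(cc + radius / pw)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc_g = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        dist2 = ((rr - cr) * ph) ** 2 + ((cc_g - cc) * pw) ** 2
        grid[r0:r1, c0:c1] |= dist2 <= radius**2
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    vegetated = np.nan_to_num(ndvi, nan=-2.0) > cfg.ndvi_threshold
    valid = (red != master.nodata) & (nir != master.nodata)
    return Mask(grid & vegetated & valid, "tree", scene_id, (pw, ph))


def adapt_tree_mask(
    master_mask: Mask, target_meta: SceneMetadata, cfg: TreeMaskConfig | None = None
) -> Mask:
    """Shift the master tree mask to a target acquisition's viewing geometry.

    Crown tops appear displaced by d = canopy_height * tan(off-nadir) along the
    satellite azimuth (clockwise from north); the mask is translated by d
    rounded to whole-pixel row/column offsets on the mask's own grid. Pixels
    shifted off the grid are dropped, so the mask cardinality never increases;
    at nadir the mask is returned unchanged.
    """
    cfg = cfg or TreeMaskConfig()
    cfg.validate()
    if target_meta.sat_offnadir_deg >= 90:
        raise ConfigError("sat_offnadir_deg must be < 90")
    theta = math.radians(target_meta.sat_offnadir_deg)
    d = cfg.canopy_height_m * math.tan(theta)
    az = math.radians(target_meta.sat_azimuth_deg)
    dx, dy = d * math.sin(az), d * math.cos(az)
    pw, ph = master_mask.pixel_size_m
    dc = round(dx / pw)
    dr = round(-dy / ph)  # map north (+y) is decreasing row
    grid = np.zeros_like(master_mask.grid)
    h, w = grid.shape
    src_r0, src_r1 = max(0, -dr), min(h, h - dr)
    src_c0, src_c1 = max(0, -dc), min(w, w - dc)
    if src_r0 < src_r1 and src_c0 < src_c1:
        grid[src_r0 + dr : src_r1 + dr, src_c0 + dc : src_c1 + dc] = master_mask.grid[
            src_r0:src_r1, src_c0:src_c1
        ]
    return Mask(grid, "tree", target_meta.scene_id, master_mask.pixel_size_m)


def combine_masks(masks) -> Mask:
    """Pixelwise OR of aligned masks."""
    masks = list(masks)
    if not masks:
        raise SchemaError("combine_masks: empty mask list")
    shape = masks[0].grid.shape
    for m in masks[1:]:
        if m.grid.shape != shape:
            raise SchemaError("combine_masks: dimension mismatch")
    grid = np.zeros(shape, dtype=bool)
    for m in masks:
        grid |= m.grid
    kind = masks[0].kind if len({m.kind for m in masks}) == 1 else "combined"
    return Mask(grid, kind, masks[0].source_scene_id, masks[0].pixel_size_m)
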