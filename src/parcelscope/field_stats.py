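"""Object-based per-field signature extraction.

For every farm parcel and every co-registered acquisition this module
computes the record that feeds a crop spectrotemporal signature library:

* a negative buffer (default 2 m) shrinks the parcel to exclude boundary
  pixels contaminated by edge vegetation;
* pixels are selected by the pixel-centre-in-polygon rule; cloud and tree
  masks remove contaminated pixels (``n_total`` counts polygon pixels,
  ``n_used`` the unmasked ones that contribute to statistics);
* spectral statistics are the direct (population) moments — mean, variance,
  moment-ratio skewness g1 = m3 / m2^(3/2) — plus the band-to-band
  correlation and covariance matrices;
* nine vegetation indices (NDVI, green NDVI, EVI, TCARI, simple ratio,
  SARVI, SAVI, MSAVI2, NIR2-based NDVI) are evaluated pixelwise and
  summarised by mean and population standard deviation;
* texture is characterised by the grey-level co-occurrence matrix (GLCM) over
  the parcel's irregular support — only pixel pairs whose two members both
  lie inside the usable field contribute — for four angles (0, 45, 90, 135
  degrees), two quantisations (64 and 256 grey levels, per-field min-max
  stretch) and the thirteen Haralick descriptors with entropies in bits.

Undefined statistics (empty fields, constant bands, absent sensor bands,
degenerate co-occurrence) are NaN in memory and empty cells in the CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import shapely

from .errors import ConfigError, DegeneracyError, SchemaError
from .masks import Mask, combine_masks
from .raster_io import ROLE_ORDER, FieldPolygon, Scene, SceneMetadata


# ---------------------------------------------------------------------------
# Parameter and record types
# ---------------------------------------------------------------------------

@dataclass
class VIParams:
    """Constants of the soil/aerosol-adjusted indices."""

    L: float = 0.5  # soil-adjustment constant (SAVI, SARVI)
    gamma: float = 1.0  # aerosol-resistance constant (SARVI)

    def validate(self) -> None:
        if self.L < 0:
            raise ConfigError("L must be >= 0")


@dataclass
class GLCMSpec:
    """One co-occurrence configuration (grey levels, angle, displacement)."""

    grey_levels: int = 64
    angle_deg: int = 0
    distance_px: int = 1
    symmetric: bool = True

    def validate(self) -> None:
        if self.grey_levels < 2:
            raise ConfigError("grey_levels must be >= 2")
        if self.angle_deg not in (0, 45, 90, 135):
            raise ConfigError("angle_deg must be one of 0, 45, 90, 135")
        if self.distance_px < 1:
            raise ConfigError("distance_px must be >= 1")


@dataclass
class FieldSpectralRecord:
    scene_id: str
    field_id: str
    crop: str
    date: str
    n_total: int
    n_used: int
    band_roles: list[str]
    band_stats: dict[str, tuple[float, float, float]]  # role -> (mean, var, skew)
    corr: dict[tuple[str, str], float]
    cov: dict[tuple[str, str], float]
    vi: dict[str, tuple[float, float]]  # index -> (mean, sd)


@dataclass
class FieldTextureRecord:
    scene_id: str
    field_id: str
    grey_levels: int
    angle_deg: int
    descriptors: dict[str, float]


@dataclass
class ExtractionParams:
    """Everything tunable about per-field extraction."""

    buffer_m: float = 2.0
    vi: VIParams = dc_field(default_factory=VIParams)
    grey_levels: tuple[int, ...] = (64, 256)
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    glcm_distance_px: int = 1
    glcm_symmetric: bool = True
    texture_band: str | None = None  # None = pan if present, else nir1


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def buffer_field(poly: FieldPolygon, buffer_m: float) -> FieldPolygon | None:
    """Euclidean inward offset of the parcel boundary; None if it collapses."""
    if buffer_m < 0:
        raise ConfigError("buffer_m must be >= 0")
    shp = poly.shapely()
    if buffer_m == 0:
        return poly
    inner = shp.buffer(-buffer_m)
    if inner.is_empty or inner.area <= 0:
        return None
    if inner.geom_type == "MultiPolygon":  # keep the dominant part
        inner = max(inner.geoms, key=lambda g: g.area)
    ring = [tuple(v) for v in inner.exterior.coords]
    return FieldPolygon(poly.field_id, poly.crop, ring)


def field_pixels(
    scene: Scene,
    poly: FieldPolygon | None,
    mask: Mask | None = None,
    poly_crs: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean grids of (total, used) pixels for an (already buffered) parcel.

    ``total`` holds pixels whose centre falls inside the polygon and carry data
    on every band; ``used`` removes masked pixels. A collapsed (None) polygon
    yields two empty grids.
    """
    if poly_crs is not None and poly_crs != scene.crs_id:
        raise SchemaError(f"polygon CRS {poly_crs} differs from scene CRS {scene.crs_id}")
    total = np.zeros((scene.height, scene.width), dtype=bool)
    if poly is not None:
        shp = poly.shapely()
        xmin, ymin, xmax, ymax = shp.bounds
        r0, c0 = scene.world_to_pixel(xmin, ymax)
        r1, c1 = scene.world_to_pixel(xmax, ymin)
        r0 = max(0, int(math.floor(r0)))
        c0 = max(0, int(math.floor(c0)))
        r1 = min(scene.height - 1, int(math.ceil(r1)))
        c1 = min(scene.width - 1, int(math.ceil(c1)))
        if r0 <= r1 and c0 <= c1:
            rows = np.arange(r0, r1 + 1)
            cols = np.arange(c0, c1 + 1)
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            xs, ys = scene.pixel_to_world(rr.ravel(), cc.ravel())
            inside = shapely.contains_xy(shp, xs, ys).reshape(rr.shape)
            total[r0 : r1 + 1, c0 : c1 + 1] = inside
        total &= scene.valid_mask()
    used = total.copy()
    if mask is not None:
        if mask.grid.shape != total.shape:
            raise SchemaError("mask dimensions differ from scene dimensions")
        used &= ~mask.grid
    return total, used


# ---------------------------------------------------------------------------
# Spectral moments
# ---------------------------------------------------------------------------

def spectral_moments(
    values: dict[str, np.ndarray],
) -> tuple[
    dict[str, tuple[float, float, float]],
    dict[tuple[str, str], float],
    dict[tuple[str, str], float],
]:
    """Population moments and band-pair correlation/covariance.

    mean = sum(x)/n, variance = central moment m2, skewness = m3 / m2^(3/2);
    covariance is the population cross-moment and correlation its normalised
    form. With n = 0 every statistic is NaN; with m2 = 0 skewness and the
    correlations involving that band are NaN.
    """
    roles = [r for r in ROLE_ORDER if r in values]
    arrays = {r: np.asarray(values[r], dtype=np.float64).ravel() for r in roles}
    lengths = {len(a) for a in arrays.values()}
    if len(lengths) > 1:
        raise SchemaError(f"ragged band lengths: {sorted(lengths)}")
    n = lengths.pop() if lengths else 0

    stats: dict[str, tuple[float, float, float]] = {}
    centred: dict[str, np.ndarray] = {}
    for r in roles:
        x = arrays[r]
        if n == 0:
            stats[r] = (np.nan, np.nan, np.nan)
            centred[r] = x
            continue
        mean = float(x.mean())
        d = x - mean
        m2 = float(np.mean(d**2))
        m3 = float(np.mean(d**3))
        # snap float rounding of a constant band to an exact zero variance
        if m2 <= (1e-10 * (abs(mean) + 1e-15)) ** 2:
            m2 = 0.0
        skew = m3 / m2**1.5 if m2 > 0 else np.nan
        stats[r] = (mean, m2, skew)
        centred[r] = d
    corr: dict[tuple[str, str], float] = {}
    cov: dict[tuple[str, str], float] = {}
    for i, ri in enumerate(roles):
        for rj in roles[i + 1 :]:
            if n == 0:
                corr[(ri, rj)] = np.nan
                cov[(ri, rj)] = np.nan
                continue
            c = float(np.mean(centred[ri] * centred[rj]))
            cov[(ri, rj)] = c
            vi_, vj_ = stats[ri][1], stats[rj][1]
            corr[(ri, rj)] = c / math.sqrt(vi_ * vj_) if vi_ > 0 and vj_ > 0 else np.nan
    return stats, corr, cov


# ---------------------------------------------------------------------------
# Vegetation indices
# ---------------------------------------------------------------------------

def _safe_div(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out


def vegetation_indices(
    band_values: dict[str, np.ndarray], params: VIParams | None = None
) -> dict[str, np.ndarray]:
    """Pixelwise vegetation indices from per-role reflectance arrays.

    Indices whose bands the sensor lacks (TCARI without a red-edge band,
    NIR2-NDVI without a second NIR band) are absent from the result; a
    division by zero yields NaN for that pixel only.
    """
    params = params or VIParams()
    params.validate()
    v = {k: np.asarray(a, dtype=np.float64) for k, a in band_values.items()}
    out: dict[str, np.ndarray] = {}
    if not {"red", "nir1"} <= v.keys():
        return out
    r, nir = v["red"], v["nir1"]
    out["ndvi"] = _safe_div(nir - r, nir + r)
    if "green" in v:
        g = v["green"]
        out["gndvi"] = _safe_div(nir - g, nir + g)
    if "blue" in v:
        b = v["blue"]
        out["evi"] = _safe_div(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0)
        rrb = r - params.gamma * (b - r)
        out["sarvi"] = _safe_div((1.0 + params.L) * (nir - rrb), nir + rrb + params.L)
    if "rededge" in v and "green" in v:
        re = v["rededge"]
        out["tcari"] = 3.0 * ((re - r) - 0.2 * (re - v["green"]) * _safe_div(re, r))
    out["simple_ratio"] = _safe_div(nir, r)
    out["savi"] = _safe_div((1.0 + params.L) * (nir - r), nir + r + params.L)
    disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - r)
    with np.errstate(invalid="ignore"):
        out["msavi2"] = np.where(disc >= 0, (2.0 * nir + 1.0 - np.sqrt(np.abs(disc))) / 2.0, np.nan)
    if "nir2" in v:
        n2 = v["nir2"]
        out["ndvi_nir2"] = _safe_div(n2 - r, n2 + r)
    return out


def field_vi_summary(
    scene: Scene,
    poly: FieldPolygon | None,
    mask: Mask | None = None,
    params: VIParams | None = None,
) -> dict[str, tuple[float, float]]:
    """Mean and population sd of each index over the parcel's usable pixels.

    Pixels where an index is undefined are ignored for that index; an index
    undefined everywhere (or an empty parcel) reports (NaN, NaN).
    """
    _, used = field_pixels(scene, poly, mask)
    band_values = {role: scene.band(role)[used] for role in scene.roles()}
    indices = vegetation_indices(band_values, params)
    out: dict[str, tuple[float, float]] = {}
    for name, arr in indices.items():
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            out[name] = (np.nan, np.nan)
        else:
            out[name] = (float(finite.mean()), float(finite.std()))
    return out


# ---------------------------------------------------------------------------
# GLCM and Haralick descriptors
# ---------------------------------------------------------------------------

#: (row, col) pixel offsets per angle for distance d (rows grow southward,
#: so 45 degrees points up-right on the map)
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize(values: np.ndarray, grey_levels: int, usable: np.ndarray | None = None) -> np.ndarray:
    """Linear min-max quantisation of a field's values into grey levels.

    Returns an int grid with levels 0..G-1 inside ``usable`` and -1 outside.
    A constant field quantises to level 0 everywhere.
    """
    values = np.asarray(values, dtype=np.float64)
    if usable is None:
        usable = np.isfinite(values)
    out = np.full(values.shape, -1, dtype=np.int64)
    if not usable.any():
        return out
    lo = values[usable].min()
    hi = values[usable].max()
    if hi <= lo:
        out[usable] = 0
        return out
    lv = np.floor((values[usable] - lo) / (hi - lo) * grey_levels).astype(np.int64)
    out[usable] = np.clip(lv, 0, grey_levels - 1)
    return out


def glcm(levels: np.ndarray, spec: GLCMSpec) -> np.ndarray:
    """Normalised grey-level co-occurrence matrix over an irregular support.

    ``levels`` is an integer grid with values in 0..G-1 inside the field and
    -1 elsewhere; only displaced pixel pairs with both members inside the
    field contribute. When ``spec.symmetric`` the transpose counts are added
    before normalisation. A field with no valid pair is degenerate.
    """
    spec.validate()
    levels = np.asarray(levels)
    G = spec.grey_levels
    if levels.ndim != 2:
        raise SchemaError("levels grid must be 2-D")
    if levels.max(initial=-1) >= G:
        raise SchemaError("levels exceed grey_levels - 1")
    dr, dc = _ANGLE_OFFSETS[spec.angle_deg]
    dr *= spec.distance_px
    dc *= spec.distance_px
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    counts = np.zeros((G, G), dtype=np.float64)
    if r0 < r1 and c0 < c1:
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            np.add.at(counts, (a[ok], b[ok]), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegeneracyError("no valid co-occurrence pairs in field")
    return counts / total


def haralick(P: np.ndarray) -> dict[str, float]:
    """The thirteen Haralick texture descriptors of a normalised GLCM.

    Indices are 0-based; entropies use log base 2 (bits). The information
    measure of correlation reported as ``f_imc`` is the first measure; the
    second is returned as ``f_imc2_aux``. The maximal correlation coefficient
    is the square root of the second-largest eigenvalue of the chain matrix
    Q(i,j) = sum_k P(i,k) P(j,k) / (p_x(i) p_y(k)); NaN on numerical failure.
    Statistics that require a spread (correlation, imc) are NaN for
    degenerate (single-level) matrices.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise SchemaError("P must be a square matrix")
    if not math.isclose(float(P.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
        raise SchemaError("P must be normalized to sum 1")
    G = P.shape[0]
    i = np.arange(G)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    def ent(p):  # entropy in bits over the nonzero support
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    d = {}
    d["f_asm"] = float((P**2).sum())
    d["f_contrast"] = float((((ii - jj) ** 2) * P).sum())
    if var_x > 0 and var_y > 0:
        d["f_correlation"] = float(((ii * jj * P).sum() - mu_x * mu_y) / math.sqrt(var_x * var_y))
    else:
        d["f_correlation"] = np.nan
    d["f_variance"] = float((((ii - mu_x) ** 2) * P).sum())
    d["f_homogeneity"] = float((P / (1.0 + (ii - jj) ** 2)).sum())

    k_sum = np.arange(2 * G - 1)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    d["f_sum_avg"] = float((k_sum * p_sum).sum())
    d["f_sum_var"] = float((((k_sum - d["f_sum_avg"]) ** 2) * p_sum).sum())
    d["f_sum_entropy"] = ent(p_sum)
    d["f_entropy"] = ent(P.ravel())

    k_diff = np.arange(G)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    mu_d = float((k_diff * p_diff).sum())
    d["f_diff_var"] = float((((k_diff - mu_d) ** 2) * p_diff).sum())
    d["f_diff_entropy"] = ent(p_diff)

    hx, hy, hxy = ent(px), ent(py), d["f_entropy"]
    nz = P > 0
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        hxy1 = float(-(P[nz] * np.log2(pxy[nz])).sum())
        pos = pxy > 0
        hxy2 = float(-(pxy[pos] * np.log2(pxy[pos])).sum())
    denom = max(hx, hy)
    d["f_imc"] = (hxy - hxy1) / denom if denom > 0 else np.nan
    d["f_imc2_aux"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    d["f_max_corr_coeff"] = _max_corr_coeff(P, px, py)
    return d


def _max_corr_coeff(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    rows = px > 0
    cols = py > 0
    if rows.sum() < 2 or cols.sum() < 2:
        return np.nan
    Psub = P[np.ix_(rows, cols)]
    Q = (Psub / px[rows, None]) @ (Psub / py[None, cols]).T
    try:
        ev = np.linalg.eigvals(Q)
    except np.linalg.LinAlgError:
        return np.nan
    ev = np.sort(np.real(ev))
    second = ev[-2]
    if not np.isfinite(second):
        return np.nan
    return float(math.sqrt(max(0.0, min(1.0, second))))


# ---------------------------------------------------------------------------
# Per-field drivers
# ---------------------------------------------------------------------------

def field_texture(
    scene: Scene,
    poly: FieldPolygon | None,
    mask: Mask | None,
    scene_id: str,
    params: ExtractionParams | None = None,
) -> list[FieldTextureRecord]:
    """All grey-level x angle texture records for one (buffered) parcel.

    Emits one record per combination (default 2 x 4 = 8); parcels with fewer
    than four usable pixels, or a degenerate co-occurrence, get records whose
    descriptors are all undefined.
    """
    params = params or ExtractionParams()
    band_role = params.texture_band or ("pan" if scene.has_band("pan") else "nir1")
    band = scene.band(band_role).astype(np.float64)
    _, used = field_pixels(scene, poly, mask)
    field_id = poly.field_id if poly is not None else "collapsed"
    records = []
    for G in params.grey_levels:
        levels = quantize(band, G, usable=used)
        for angle in params.angles_deg:
            spec = GLCMSpec(G, angle, params.glcm_distance_px, params.glcm_symmetric)
            desc: dict[str, float]
            if used.sum() < 4:
                desc = {}
            else:
                try:
                    desc = haralick(glcm(levels, spec))
                except DegeneracyError:
                    desc = {}
            records.append(FieldTextureRecord(scene_id, field_id, G, angle, desc))
    return records


def extract_all(
    scene: Scene,
    metadata: SceneMetadata,
    fields: Sequence[FieldPolygon],
    masks: Mask | Iterable[Mask] | None,
    params: ExtractionParams | None = None,
) -> tuple[list[FieldSpectralRecord], list[FieldTextureRecord]]:
    """One spectral record per parcel plus its texture records for one scene.

    A parcel entirely masked out (or collapsed by the buffer) still yields a
    record with ``n_used`` = 0 and undefined statistics, so the signature
    library keeps an explicit row for every parcel and date.
    """
    params = params or ExtractionParams()
    if masks is None:
        mask = None
    elif isinstance(masks, Mask):
        mask = masks
    else:
        ms = list(masks)
        mask = combine_masks(ms) if ms else None
    date = metadata.acquisition_time.date().isoformat()
    roles = scene.roles()
    spectral: list[FieldSpectralRecord] = []
    texture: list[FieldTextureRecord] = []
    for poly in fields:
        inner = buffer_field(poly, params.buffer_m)
        total, used = field_pixels(scene, inner, mask)
        values = {r: scene.band(r)[used] for r in roles}
        band_stats, corr, cov = spectral_moments(values)
        indices = vegetation_indices(values, params.vi)
        vi_summary: dict[str, tuple[float, float]] = {}
        for name, arr in indices.items():
            finite = arr[np.isfinite(arr)]
            vi_summary[name] = (
                (float(finite.mean()), float(finite.std())) if finite.size else (np.nan, np.nan)
            )
        spectral.append(
            FieldSpectralRecord(
                scene_id=metadata.scene_id,
                field_id=poly.field_id,
                crop=poly.crop,
                date=date,
                n_total=int(total.sum()),
                n_used=int(used.sum()),
                band_roles=roles,
                band_stats=band_stats,
                corr=corr,
                cov=cov,
                vi=vi_summary,
            )
        )
        tex = field_texture(scene, inner, mask, metadata.scene_id, params)
        for t in tex:
            t.field_id = poly.field_id
        texture.extend(tex)
    return spectral, texture
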