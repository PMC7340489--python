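"""Tree-crown based image co-registration.

Isolated tree crowns present a bell-shaped intensity surface in the NIR band
and persist across a season, which makes them usable tie points in landscapes
that lack paved roads. The steps are:

1. :func:`detect_blobs` — crowns as maxima of the scale-normalised
   Laplacian-of-Gaussian response over position and scale (a geometric sigma
   ladder), with sub-pixel quadratic refinement in x, y and log-scale;
2. :func:`select_master` — the reference scene of a site is the acquisition
   with the longest tree shadows (lowest sun; proxy cot(sun elevation)), which
   renders crowns most distinctly;
3. :func:`correct_parallax` — crown centroids are apparent positions displaced
   by canopy_height * tan(off-nadir) along the satellite azimuth; matching
   operates on the corrected ground positions;
4. :func:`match_tiepoints` — mutual-nearest-neighbour pairing within a search
   radius, scored by detector response and scale similarity;
5. :func:`estimate_correction` — a random-sample-consensus fit (translation by
   default, affine by flag) refit on its inliers, reporting per-axis RMSE;
6. :func:`apply_correction` — resampling of the target scene onto the master
   grid.

:func:`evaluate_against_controls` computes the residual statistics used to
assess registration quality against independent control points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigError, DegeneracyError, InsufficientDataError, SchemaError
from .raster_io import Scene, SceneMetadata


@dataclass
class Blob:
    """A detected tree-crown candidate in map coordinates."""

    x_m: float
    y_m: float
    sigma_m: float
    response: float


@dataclass
class DetectorConfig:
    sigma_min_m: float = 3.0
    sigma_max_m: float = 10.0
    n_scales: int = 10
    response_threshold: float = 0.02
    max_blobs: int = 500

    def validate(self) -> None:
        if not 0 < self.sigma_min_m < self.sigma_max_m:
            raise ConfigError("sigma range must satisfy 0 < sigma_min_m < sigma_max_m")
        if self.n_scales < 3:
            raise ConfigError("n_scales must be >= 3")
        if self.max_blobs < 1:
            raise ConfigError("max_blobs must be >= 1")


@dataclass
class TiePointPair:
    master_xy_m: tuple[float, float]
    target_xy_m: tuple[float, float]
    match_score: float
    residual_m: float | None = None


@dataclass
class GeoCorrection:
    """A fitted target->master geometric transform with its residual summary."""

    model: str  # "translation" | "affine"
    parameters: tuple[float, ...]  # (tx, ty) or (a, b, c, d, e, f)
    rmse_x_m: float
    rmse_y_m: float
    n_inliers: int

    def transform(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.model == "translation":
            tx, ty = self.parameters
            return xy + np.array([tx, ty])
        a, b, c, d, e, f = self.parameters
        return np.column_stack([a * xy[:, 0] + b * xy[:, 1] + c, d * xy[:, 0] + e * xy[:, 1] + f])


def _quadratic_offset(m1: float, m0: float, p1: float) -> float:
    """Sub-sample offset of a parabola through three samples; 0 when flat."""
    denom = m1 - 2.0 * m0 + p1
    if denom >= 0 or abs(denom) < 1e-300:
        return 0.0
    off = 0.5 * (m1 - p1) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_blobs(scene: Scene, band_role: str = "nir1", cfg: DetectorConfig | None = None) -> list[Blob]:
    """Detect bright blobs as scale-normalised LoG maxima over (x, y, sigma).

    Returns blobs sorted by response (descending), truncated to
    ``cfg.max_blobs``, with centroids and scales in map metres.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    img = scene.band(band_role).astype(np.float64)
    valid = img != scene.nodata
    if not valid.any():
        return []
    if not valid.all():
        img = np.where(valid, img, np.median(img[valid]))

    _, _, pw, ph = scene.geotransform
    px = 0.5 * (pw + ph)
    sigmas_px = np.geomspace(cfg.sigma_min_m / px, cfg.sigma_max_m / px, cfg.n_scales)
    stack = np.empty((cfg.n_scales, *img.shape))
    for i, s in enumerate(sigmas_px):
        stack[i] = -(s**2) * ndimage.gaussian_laplace(img, s)

    local_max = ndimage.maximum_filter(stack, size=3, mode="nearest")
    peaks = np.argwhere((stack == local_max) & (stack > cfg.response_threshold))

    log_sig = np.log(sigmas_px)
    blobs: list[Blob] = []
    h, w = img.shape
    for si, r, c in peaks:
        # a genuine scale-space maximum is interior both in space and in
        # scale; ladder-edge responses belong to structures outside the
        # configured sigma range (noise speckle, whole parcels)
        if r == 0 or r == h - 1 or c == 0 or c == w - 1:
            continue
        if si == 0 or si == cfg.n_scales - 1:
            continue
        resp = stack[si, r, c]
        dr = _quadratic_offset(stack[si, r - 1, c], resp, stack[si, r + 1, c])
        dc = _quadratic_offset(stack[si, r, c - 1], resp, stack[si, r, c + 1])
        ds = _quadratic_offset(stack[si - 1, r, c], resp, stack[si + 1, r, c])
        step = log_sig[1] - log_sig[0]
        sigma_px = math.exp(log_sig[si] + ds * step)
        x_m, y_m = scene.pixel_to_world(r + dr, c + dc)
        blobs.append(Blob(float(x_m), float(y_m), sigma_px * px, float(resp)))

    blobs.sort(key=lambda b: (-b.response, b.x_m, b.y_m))
    return blobs[: cfg.max_blobs]


def filter_blobs_near_bright(
    scene: Scene,
    blobs: Sequence[Blob],
    band_role: str = "blue",
    max_reflectance: float = 0.5,
    clearance_sigmas: float = 2.0,
) -> list[Blob]:
    """Drop blobs in or near bright pixels of a short-wavelength band.

    Clouds are far brighter in the blue band than any crown or soil, and a
    crown partially under cloud yields a displaced centroid, so tie points
    must keep clear of them: a blob is discarded when any pixel within
    ``clearance_sigmas * sigma`` of its centre exceeds ``max_reflectance``.
    """
    band = scene.band(band_role)
    h, w = band.shape
    _, _, pw, ph = scene.geotransform
    keep = []
    for b in blobs:
        r_f, c_f = scene.world_to_pixel(b.x_m, b.y_m)
        rad_r = clearance_sigmas * b.sigma_m / ph
        rad_c = clearance_sigmas * b.sigma_m / pw
        r0, r1 = max(0, int(r_f - rad_r)), min(h, int(r_f + rad_r) + 2)
        c0, c1 = max(0, int(c_f - rad_c)), min(w, int(c_f + rad_c) + 2)
        window = band[r0:r1, c0:c1]
        if window.size and float(window.max()) > max_reflectance:
            continue
        keep.append(b)
    return keep


def select_master(metadata_list: Sequence[SceneMetadata]) -> str:
    """Scene id with the longest tree-shadow proxy, cot(sun elevation).

    Ties break on earliest acquisition time, then lexicographic scene id.
    """
    if not metadata_list:
        raise InsufficientDataError("select_master: empty metadata list")

    def key(m: SceneMetadata):
        cot = 1.0 / math.tan(math.radians(m.sun_elevation_deg))
        return (-cot, m.acquisition_time, m.scene_id)

    return min(metadata_list, key=key).scene_id


def correct_parallax(
    blobs: Sequence[Blob], metadata: SceneMetadata, canopy_height_m: float = 10.0
) -> list[Blob]:
    """Remove the first-order parallax displacement of elevated crown tops.

    A crown top of height h viewed at off-nadir angle theta appears displaced
    by d = h * tan(theta) along the satellite azimuth; the corrected ground
    position is the apparent position minus that displacement. At nadir this
    is the identity.
    """
    theta = math.radians(metadata.sat_offnadir_deg)
    d = canopy_height_m * math.tan(theta)
    az = math.radians(metadata.sat_azimuth_deg)
    dx, dy = d * math.sin(az), d * math.cos(az)
    return [Blob(b.x_m - dx, b.y_m - dy, b.sigma_m, b.response) for b in blobs]


def match_tiepoints(
    master_blobs: Sequence[Blob],
    target_blobs: Sequence[Blob],
    search_radius_m: float,
    coarse_shift_m: tuple[float, float] = (0.0, 0.0),
    min_score_frac: float = 0.0,
) -> list[TiePointPair]:
    """One-to-one mutual-nearest-neighbour pairing of blob centroids.

    Each target blob, after removing ``coarse_shift_m``, is paired with the
    nearest master blob within ``search_radius_m``; the pair survives only if
    the relation is mutual. ``match_score`` is the weaker response times the
    scale-similarity ratio min(sigma)/max(sigma). With ``min_score_frac`` > 0
    only the strongest candidates survive: pairs scoring below that fraction
    of the best pair's score are dropped before the fit.
    """
    if search_radius_m <= 0:
        raise ConfigError("search_radius_m must be positive")
    if not master_blobs or not target_blobs:
        return []
    m_xy = np.array([[b.x_m, b.y_m] for b in master_blobs])
    t_xy = np.array([[b.x_m, b.y_m] for b in target_blobs]) - np.asarray(coarse_shift_m)
    m_tree = cKDTree(m_xy)
    t_tree = cKDTree(t_xy)
    d_mt, nearest_m = m_tree.query(t_xy)
    _, nearest_t = t_tree.query(m_xy)
    pairs = []
    for ti, (mi, dist) in enumerate(zip(nearest_m, d_mt)):
        if dist > search_radius_m or nearest_t[mi] != ti:
            continue
        mb, tb = master_blobs[mi], target_blobs[ti]
        scale_sim = min(mb.sigma_m, tb.sigma_m) / max(mb.sigma_m, tb.sigma_m)
        pairs.append(
            TiePointPair(
                master_xy_m=(mb.x_m, mb.y_m),
                target_xy_m=(tb.x_m, tb.y_m),
                match_score=min(mb.response, tb.response) * scale_sim,
            )
        )
    if pairs and min_score_frac > 0:
        cut = min_score_frac * max(p.match_score for p in pairs)
        pairs = [p for p in pairs if p.match_score >= cut]
    return pairs


def _fit_translation(m: np.ndarray, t: np.ndarray) -> tuple[float, ...]:
    d = (m - t).mean(axis=0)
    return (float(d[0]), float(d[1]))


def _fit_affine(m: np.ndarray, t: np.ndarray) -> tuple[float, ...]:
    A = np.column_stack([t, np.ones(len(t))])
    coef, *_ = np.linalg.lstsq(A, m, rcond=None)
    (a, d), (b, e), (c, f) = coef
    return (float(a), float(b), float(c), float(d), float(e), float(f))


def _apply_params(model: str, params, xy: np.ndarray) -> np.ndarray:
    return GeoCorrection(model, params, 0.0, 0.0, 0).transform(xy)


def estimate_correction(
    pairs: Sequence[TiePointPair],
    model: str = "translation",
    inlier_tol_m: float = 3.0,
    seed: int = 0,
    n_iterations: int = 500,
) -> GeoCorrection:
    """Robust consensus fit of the target->master transform.

    Random-sample consensus with a fixed seed: minimal samples propose a
    transform, the largest inlier set (ties: lowest RMS) wins, and the final
    parameters are a least-squares refit on those inliers. Residuals are
    written back onto every pair; RMSE is per signed axis over inliers.
    """
    if model not in ("translation", "affine"):
        raise ConfigError(f"unknown model {model!r}")
    min_n = 1 if model == "translation" else 3
    if len(pairs) < min_n:
        raise InsufficientDataError(f"{model} needs >= {min_n} tie-point pairs, got {len(pairs)}")
    m = np.array([p.master_xy_m for p in pairs], dtype=float)
    t = np.array([p.target_xy_m for p in pairs], dtype=float)
    n = len(pairs)
    rng = np.random.default_rng(seed)

    if model == "translation":
        samples = [np.array([i]) for i in range(n)] if n <= n_iterations else [
            rng.integers(0, n, size=1) for _ in range(n_iterations)
        ]
        fit = _fit_translation
    else:
        samples = [rng.choice(n, size=3, replace=False) for _ in range(n_iterations)]
        fit = _fit_affine

    best = None  # (count, -rms, params, inlier_mask)
    scale = max(np.ptp(t[:, 0]), np.ptp(t[:, 1]), 1.0)
    for idx in samples:
        ts, ms = t[idx], m[idx]
        if model == "affine":
            area = 0.5 * abs(
                (ts[1, 0] - ts[0, 0]) * (ts[2, 1] - ts[0, 1])
                - (ts[2, 0] - ts[0, 0]) * (ts[1, 1] - ts[0, 1])
            )
            if area < 1e-9 * scale**2:
                continue
        params = fit(ms, ts)
        res = np.linalg.norm(_apply_params(model, params, t) - m, axis=1)
        inliers = res <= inlier_tol_m
        count = int(inliers.sum())
        if count < min_n:
            continue
        rms = float(np.sqrt(np.mean(res[inliers] ** 2)))
        cand = (count, -rms, params, inliers)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise DegeneracyError(f"{model}: no non-degenerate consensus sample found")

    inliers = best[3]
    if model == "affine" and int(inliers.sum()) >= 3:
        ti, mi = t[inliers], m[inliers]
        area_ok = np.ptp(ti[:, 0]) > 1e-9 * scale and np.ptp(ti[:, 1]) > 1e-9 * scale
        if not area_ok:
            raise DegeneracyError("affine: inlier tie points are collinear")
    params = fit(m[inliers], t[inliers])
    # one re-classification pass with the refit parameters, then final refit
    res = np.linalg.norm(_apply_params(model, params, t) - m, axis=1)
    inliers = res <= inlier_tol_m
    if int(inliers.sum()) >= min_n:
        params = fit(m[inliers], t[inliers])
        res = np.linalg.norm(_apply_params(model, params, t) - m, axis=1)
        inliers = res <= inlier_tol_m

    pred = _apply_params(model, params, t)
    signed = pred - m
    for p, r in zip(pairs, np.linalg.norm(signed, axis=1)):
        p.residual_m = float(r)
    in_signed = signed[inliers]
    rmse_x = float(np.sqrt(np.mean(in_signed[:, 0] ** 2)))
    rmse_y = float(np.sqrt(np.mean(in_signed[:, 1] ** 2)))
    return GeoCorrection(model, params, rmse_x, rmse_y, int(inliers.sum()))


def apply_correction(scene: Scene, corr: GeoCorrection, resampling: str = "nearest") -> Scene:
    """Resample a target scene onto the master grid under the fitted transform.

    The output pixel at map position p takes the input value at the inverse
    transform of p; all bands are resampled identically and uncovered pixels
    become nodata.
    """
    if resampling not in ("nearest", "bilinear"):
        raise ConfigError(f"resampling must be nearest|bilinear, got {resampling!r}")
    if corr.model not in ("translation", "affine"):
        raise ConfigError(f"unsupported correction model {corr.model!r}")
    order = 0 if resampling == "nearest" else 1
    rows, cols = np.meshgrid(np.arange(scene.height), np.arange(scene.width), indexing="ij")
    xs, ys = scene.pixel_to_world(rows.ravel(), cols.ravel())
    if corr.model == "translation":
        tx, ty = corr.parameters
        src = np.column_stack([xs - tx, ys - ty])
    else:
        a, b, c, d, e, f = corr.parameters
        inv = np.linalg.inv(np.array([[a, b], [d, e]]))
        src = (np.column_stack([xs, ys]) - np.array([c, f])) @ inv.T
    src_r, src_c = scene.world_to_pixel(src[:, 0], src[:, 1])
    src_r = src_r.reshape(rows.shape)
    src_c = src_c.reshape(rows.shape)
    inside = (src_r >= 0) & (src_r <= scene.height - 1) & (src_c >= 0) & (src_c <= scene.width - 1)
    out = np.empty_like(scene.bands)
    for bi in range(scene.n_bands):
        out[bi] = ndimage.map_coordinates(
            scene.bands[bi], [src_r, src_c], order=order, mode="constant", cval=scene.nodata
        )
        out[bi][~inside] = scene.nodata
    return Scene(out, dict(scene.band_map), scene.geotransform, scene.crs_id, scene.nodata)


@dataclass
class ControlStats:
    """Residual statistics of scene points against independent control points."""

    mean_abs_x: float
    sd_abs_x: float
    mean_abs_y: float
    sd_abs_y: float
    min_x: float
    max_x: float
    min_y: float
    max_y: float
    rmse_x: float
    rmse_y: float


def evaluate_against_controls(scene_points, control_points) -> ControlStats:
    """Residual statistics (scene minus control) over paired control points.

    Mean/sd rows summarise absolute residuals per axis (population sd);
    min/max are signed; RMSE is the root-mean-square of signed residuals.
    """
    sp = np.atleast_2d(np.asarray(scene_points, dtype=float))
    cp = np.atleast_2d(np.asarray(control_points, dtype=float))
    if sp.shape != cp.shape or sp.shape[0] < 1 or sp.shape[1] != 2:
        raise SchemaError("scene and control point lists must be equal-length (n, 2) arrays, n >= 1")
    res = sp - cp
    ax = np.abs(res)
    return ControlStats(
        mean_abs_x=float(ax[:, 0].mean()),
        sd_abs_x=float(ax[:, 0].std()),
        mean_abs_y=float(ax[:, 1].mean()),
        sd_abs_y=float(ax[:, 1].std()),
        min_x=float(res[:, 0].min()),
        max_x=float(res[:, 0].max()),
        min_y=float(res[:, 1].min()),
        max_y=float(res[:, 1].max()),
        rmse_x=float(np.sqrt(np.mean(res[:, 0] ** 2))),
        rmse_y=float(np.sqrt(np.mean(res[:, 1] ** 2))),
    )
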