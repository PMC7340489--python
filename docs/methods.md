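# Methods

This note records the models, conventions and numerical choices behind
parcelscope, and what the synthetic experiments do and do not demonstrate.

## Coordinate and raster conventions

Scenes are north-up float32 surface-reflectance rasters in a projected CRS in
metres. Pixel (0,0) is top-left; the geotransform stores the outer corner of
that pixel and positive pixel sizes; the map coordinate *of* a pixel means its
centre; grids are half-open. Polygon membership is decided by the
pixel-centre-in-polygon rule, which makes buffered-parcel pixel counts
analytically checkable (a 10 × 10 m square with a 2 m negative buffer on a 1 m
grid contains exactly 36 centres). Reflectance is stored in [0, 1]; integer
scaled products are rejected rather than silently rescaled. Nodata is a
sentinel value (−9999); a pixel is valid only if every band holds data.

GeoTIFF I/O is implemented directly on TIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory, GDAL nodata) with a sidecar JSON carrying the
acquisition metadata and the band-role list. Geographic (unprojected) rasters
are refused, since every geometric quantity downstream is in metres.
Mosaicking uses a first-tile-wins overlap policy on a common lattice — it is
deterministic, order-documented, and idempotent.

## Tree-crown blob detection

Crowns are bright, roughly isotropic bumps in the NIR band. The detector
computes the scale-normalised Laplacian of Gaussian, −σ²∇²(G_σ∗I), on a
geometric ladder of σ (default 3–10 m, 10 scales) and keeps local maxima of
the 3-D (x, y, σ) response stack above a threshold (default 0.02; a crown of
amplitude A peaks near A/2, and the LoG response to 1% reflectance noise is an
order of magnitude smaller). Two deliberate restrictions:

* maxima must be **interior in scale** — a response still rising at the ladder
  edge belongs to a structure outside the configured crown-size range (noise
  speckle below, whole parcels above), and its scale estimate would be
  meaningless;
* positions and scales are refined by one-dimensional quadratic fits in x, y
  and log σ, giving centroid errors well below 0.2 px and scale errors of a
  few percent for isolated Gaussian crowns.

## Master selection and parallax

Crowns cast the longest shadows — and are therefore most distinct — when the
sun is low, so the master scene of a site maximises cot(sun elevation); ties
break on the earlier acquisition, then the scene id. The exact shadow-length
geometry involving the satellite position is deliberately reduced to this
proxy; the satellite-visibility refinement is a known omission.

A crown top of height *h* viewed θ off-nadir appears displaced by *h*·tan θ
along the satellite azimuth. Before matching, centroids are corrected with a
single configurable canopy height (default 10 m). Individual trees deviate
from that height, which leaves a zero-mean residual per crown; averaging over
the tie points suppresses it in the translation estimate.

## Tie points and the robust fit

Matching is mutual-nearest-neighbour within a search radius, scored by the
weaker detector response times the scale-similarity ratio min(σ)/max(σ). Only
the strongest candidates become control points: pairs scoring below a fraction
(default 0.4 in the pipeline) of the best pair are dropped. This filter is
what rejects weak, unstable detections (parcel corners, cloud fringes) whose
centroids jitter between acquisitions. Tie points are additionally required to
keep clear of bright blue pixels (reflectance > 0.5 within 2σ), because a
crown partially under cloud yields a displaced centroid.

The transform is fitted by random-sample consensus with a fixed seed
(translation by default — multi-temporal misregistration of orthorectified
VHSR products is dominated by a consistent shift — affine by flag, needing
three non-collinear samples). The winning inlier set (tolerance default 3 m =
1.5 pixels at 2 m GSD) is refit by least squares, re-classified once, and
refit again; the result is invariant to pair ordering and, with ≤ 30% gross
outliers, identical to the clean-data estimate to 10⁻⁶ m. RMSE is reported per
signed axis over inliers. Control-point evaluation reports mean and population
sd of absolute residuals per axis, signed extrema, and per-axis RMSE.

## Cloud mask

Masked pixels are those strictly above the (1 − p/100) order-statistic
quantile of the valid blue band, p being the metadata cloud percentage.
Strict inequality at the threshold means ties are excluded, so the masked
fraction never exceeds p — the conservative choice, and the one that makes a
constant band yield an empty mask. The assumption (clouds are the brightest
short-wavelength pixels) fails over snow, ice or bright sand; those landscapes
are outside the intended low-latitude agricultural scope.

## Tree mask

A pixel is masked when it lies within `crown_radius_factor` × σ (default 2 —
about a Gaussian's visually apparent edge) of a detected crown centroid *and*
its NDVI exceeds the threshold. The default threshold 0.2 is intentionally
*below* the conventional 0.3 vegetation cut: a missed crown pixel contaminates
the field spectra (costly), while an over-masked field pixel merely reduces
`n_used`. The master mask is adapted to other acquisitions by translating it
by the parallax displacement of the target geometry, rounded to whole pixels;
pixels shifted off-grid are dropped, so adaptation never grows the mask and is
the identity at nadir. The approach works for isolated crowns; tree rows and
closed canopies are a documented limitation, as is crown detection at coarser
(≥ 5 m) resolutions.

## Field statistics

Statistics are population moments (n-denominator) with skewness g₁ =
m₃/m₂^{3/2}, chosen as the direct moment definitions. A constant band's
variance is snapped to exactly zero when the computed m₂ is at float-rounding
level (≤ (10⁻¹⁰·|mean|)²), so skewness and correlations become undefined
markers rather than noise-driven garbage. Undefined statistics are NaN in
memory and empty CSV cells — never 0 — to keep the signature library
uncontaminated. Vegetation-index means/sds are computed over pixelwise index
values (not indices of band means; for ratios the two differ), ignoring pixels
where an index is undefined. Indices requiring red-edge or second-NIR bands
are simply absent on sensors that lack them.

## Texture

GLCMs are computed over the parcel's irregular support: only displaced pixel
pairs with both members inside the usable field contribute. Quantisation is a
linear min–max stretch of the field's own values into G levels — texture is a
within-field property, and a global stretch would couple fields through their
radiometric range. Displacement is 1 pixel, symmetric counts, four angles
(0°, 45°, 90°, 135°, measured up-the-rows so 45° points up-right on the map);
G ∈ {64, 256} in the delivered records, though the implementation accepts any
G ≥ 2. The thirteen Haralick descriptors use 0-based indices and log₂
entropies (bits). Two conventions worth recording: sum variance is computed
about the sum average (the widely accepted correction of the original print,
which references the sum entropy), and "information measure of correlation"
is the first measure, with the second emitted as an auxiliary column. The
maximal correlation coefficient is √(second-largest eigenvalue) of the chain
matrix Q(i,j) = Σₖ P(i,k)P(j,k)/(pₓ(i)p_y(k)), undefined on numerical failure
or single-level support. Fields with fewer than 2 × 2 usable pixels emit
records with undefined descriptors rather than disappearing.

## Incremental pipeline

Stage outputs are nodes of a per-site DAG generated programmatically (one
chain per scene: register → cloud mask → tree mask → statistics, plus the
master's blob and tree-mask nodes). Fingerprints are SHA-256 hashes of input
file *contents* plus a canonical JSON of the stage parameters — robust to
copying and touching, unlike timestamps. A node is stale when its fingerprint
changed, an output is missing, or any ancestor is stale. The master is chosen
at plan time and its identity is a parameter of every downstream node, so a
new non-master scene invalidates exactly its own chain while a master change
rebuilds the site. Execution is sequential in topological order; a failed
stage skips its descendants, other branches continue, and the report carries
per-stage status and timing. Outputs are byte-identical between full and
incremental runs over the same inputs and seed.

## The synthetic scenes

The simulator renders what the algorithms key on, with known ground truth:

* crowns as additive isotropic Gaussians (amplitude 0.25 reflectance,
  σ 4–8 m ≈ 2–4 px at the 2 m default GSD) on the green and NIR bands, placed
  with a minimum mutual separation of 6 σ_max and clear of parcels;
* bare-soil background (NDVI ≈ 0.14) and homogeneous rectangular parcels
  (30–60 m, canopy NDVI ≈ 0.65) with additive Gaussian sensor noise
  (default sd 0.01 reflectance);
* cloud patches region-grown to exactly round(fraction × n_pixels) pixels,
  with blue reflectance set strictly above every background value — the
  brightest-blue premise holds by construction, making the cloud mask exactly
  checkable;
* multi-acquisition sites where each scene gets a known integer-pixel
  georeferencing shift, true per-crown parallax (each tree displaced by its
  own height × tan off-nadir), fresh sensor noise, and an independent cloud
  field (clouds, unlike the landscape, do not repeat between dates).

Not modelled: sensor point-spread functions, BRDF and illumination effects,
terrain displacement, phenological change between dates, tree rows or forest
patches, and atmospheric residuals. Passing tests therefore demonstrate the
geometry, the statistics and the orchestration — not radiometric realism. The
registration study (20 pairs, 12 crowns each, 2% noise, shifts up to 10 px,
256 × 256 px scenes) and the 96 × 96 px pipeline sites are sized so the whole
suite runs in seconds; accuracy is not sensitive to scene size once a dozen
crowns are present.

## Known limitations

* Atmospheric correction and RPC/DEM orthorectification are out of scope:
  inputs are assumed to be surface reflectance on a projected grid.
* The cot(sun-elevation) shadow proxy ignores satellite-side visibility.
* Cloud masking trusts the metadata percentage; a wrong percentage translates
  directly into over- or under-masking.
* The tree mask translates rigidly under viewing geometry; it does not
  re-detect crowns per scene.
* CSV schemas are this package's own definition of the signature-library
  records.
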