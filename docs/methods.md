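# Methods

This note documents the models, conventions and numerical choices
behind `hexalign`, and what the synthetic fixtures do and do not show
about real data.

## Coordinate conventions

One convention everywhere: pixel centers, 0-based indices, x rightward,
y downward, physical units nanometers.  Images are processed at a
working pixel size (default 16 nm); transforms are expressed in nm and
scale linearly to any export pixel size.  Every stage transform is
stored as a **destination-to-source lookup**: a section is rendered at
output coordinate p by sampling the previous stage at `T(p)` (affine
stages) or `p + field(p)` (elastic stages).  Export therefore applies
the elastic fields directly and inverts only the affine stages, in
reverse chain order: ultrafine → fine → rough⁻¹ → coarse⁻¹.  Writing
the fields this way prevents the classic double-inversion bug.

## The difference-system solver

All positional unknowns — tile coordinates, sub-tile brightness
offsets, per-grid-point warp vectors — are solved from the same
weighted least-squares problem on a difference graph:

    min_x  Σ_e w_e ‖(x_dst(e) − x_src(e)) − δ_e‖²  +  λ‖x‖²

Each row of the system matrix has one +1 and one −1; the two axes are
solved independently (they couple only through the shared adjacency).
Implementation: sparse normal equations, gauge pinned by a single
diagonal entry (this selects the exact solution with x₀ = 0 from the
offset-degenerate family, without biasing it) and the final gauge fixed
by mean subtraction.  Connectivity is checked up front; a disconnected
graph is an error naming the smallest component (the sub-tile
brightness stage prevents disconnection beforehand by adding
minimum-spanning-tree edges).  Verified against a dense `lstsq` oracle
to ~1e-15 relative on ≤30-node systems; the contract in the tests is
1e-8.

Gauge-fixing policy differs by application, because the observed biases
differ: the planar (2D-montage, histogram) systems only show an offset
bias, removed by mean subtraction; the z-chain systems of the rough
alignment are 1-D in topology and additionally show linear-trend and
slow-oscillation biases, so there a per-grid-point linear fit over z is
removed per solved block, and long stacks are solved in overlapping z
blocks.  Trend removal trades a small amount of real low-frequency
signal for bias suppression: on very short stacks the fitted line
contains real structure, so desk-scale fixtures use ≥ 30 sections where
the trade is negligible (production uses 721-section context blocks).

## Normalized cross-correlation

Preprocessing before every template match: CLAHE (clip limit 30 in the
0–255 convention — mapped to `clip_limit = 30/256` for
`skimage.exposure.equalize_adapthist` — tile size 32 px at 16 nm), float
conversion, Laplacian-of-Gaussian whitening (σ = 4 px at 16 nm), and
zero-mean/unit-energy normalization.  CLAHE tile size and LoG σ scale
inversely with pixel size so the filters have fixed physical scale.

Correlation surfaces come from `skimage.feature.match_template`
(frequency-domain correlation, spatially normalized with image
integrals).  Peak localization is integer-pixel — residuals in this
pipeline are reported in whole pixels, and subpixel refinement is
deliberately absent.  Ties break toward the lowest row-major index.

**Center convention.**  The zero-delta placement of an h×w template in
an H×W image puts its top-left corner at `((H−h)//2, (W−w)//2)`; with
even dimension differences this is exact template centering, with odd
differences the half-pixel ambiguity floors.  The same convention is
used by the 2D and 3D stages.

**Partial overlap.**  The montage stage matches the quarter-crop of a
source tile against its full neighbor.  At realistic overlaps the
quadrant center lies *outside* the neighbor, so valid-mode matching is
impossible; the whitened (zero-mean) image is zero-padded by half a
template and matched in padded full mode, searching placements where
the template only partially overlaps.  Zero padding is neutral after
whitening.

**Rotation sweep.**  3D matching rotates the template through
±15° in 3° steps (fixtures use coarser sweeps); the rotated template is
cropped to the inscribed valid rectangle so no border fill enters the
correlation.  A template cut after rotating the scene by +a is
recovered at sweep angle −a (pinned by a test).

## Constrained affine fits

Four constraint levels: `full` (ordinary least squares), `rigid`
(Kabsch), `rigid+scale` (Umeyama), and `noshear` — rotation with
independent x/y scales and exactly zero shear, the 2D orthogonal
non-orthonormal Procrustes problem.  For `noshear` the optimal scales
given an angle are `s_i = (B R)_ii / D_ii` (B the src×dst
cross-moment matrix, D the per-axis source second moments), and the
reduced objective is a quadratic form in (cos θ, sin θ), maximized by
the leading eigenvector of a symmetric 2×2 matrix — a closed form,
validated in the tests against a Nelder–Mead optimizer on random
instances.  Translation is always the difference of means after the
linear part.

Decomposition uses the QR factorization `A = R(θ)·diag(s_x, s_y)·
[[1, h_x], [0, 1]]` (rotation, then scale, then shear; `shear_y` is
identically 0 in the decomposition, and reflections are carried as a
negative y-scale).  `compose ∘ decompose` is the identity to 1e-9;
shears below 1e-12 are snapped to exactly 0 so constrained fits
decompose to exact zeros.

RANSAC uses minimal samples per model, 1000 iterations by default, a
seeded generator for determinism, and a refit-reclassify polish on the
inlier set.  A pair is a *bad match* when fewer than 32 matches survive
or the fitted translation exceeds 196 µm (production values; fixtures
scale them).

## Rigid moving least squares

The rigid MLS map (weights `1/|p_i − v|^(2α)`, default α = 2) is used
for three things: interpolating/extrapolating replacement vectors for
outlier grid points, healing tears, and nothing else.  Its two key
properties — exact interpolation of controls and exact reproduction of
any global rigid transform at arbitrary query points — are asserted to
1e-6 in the tests and against an independent loop-wise implementation
of the closed form.

## 2D montaging and balancing

Intra-mFOV edges come from hexagonal lattice adjacency; inter-mFOV
edges connect tiles of different mFOVs whose *nominal footprints
actually overlap* by at least a few pixels (a plain center-distance
cutoff creates edges between non-overlapping tiles, whose garbage
deltas overwhelm the solver).  Outlier handling is two-pass: pass 1
flags deltas outside acquisition-expectation boxes (intra 768 nm, inter
15,440 × 13,440 nm); per-direction medians over the survivors are both
the pass-2 reference (intra 64 nm, inter 4,480 nm boxes) and the
replacement value for every flagged edge, which enters the solve at
weight 0.5.

Feathering uses linear edge ramps, 0.5 µm between tiles of one mFOV
and 3 µm between mFOVs (sides without a same-mFOV neighbor get the
long ramp), normalized per output pixel to a partition of unity, so
single-coverage pixels reproduce the corrected tile exactly.

Brightness correction: per-beam mean tiles over inlier tiles (rejection
by mode outside the section-histogram range and by large out-of-range
connected components > 20 % of the tile); gradient = box-filtered mean
tile divided by its mode (box 1 µm); offsets = mean-tile mode minus
overall mode, re-centered to zero mean; then the sub-tile refinement:
256-bin sub-tile histograms compared by ZNCC over lag, adjacency =
top-32 matches per sub-tile ∪ MST edges, the lag system solved by the
difference solver, and per-tile 3×3 offset grids fitted with quadratic
surfaces.  **Deviation from a plain-quantile rejection range:** the
inlier intensity range is derived as Tukey fences (quartiles ±
1.5·IQR) of the section histogram rather than 0.5 %/99.5 % tail
quantiles — tail quantiles land *inside* the artifact whenever
background pixels exceed the quantile mass, silently disabling the
component rule.  Modes are histogram argmaxes with ties toward the
lower intensity.

The absolute brightness level is a gauge the corrections cannot pin
(every correction is relative); restoration error against ground truth
is therefore measured after removing the global median difference.

## 3D contrast

Masked histogram matching via midpoint-CDF inversion: populated source
levels map through the template CDF; unpopulated levels interpolate
monotonically over the gray levels themselves, with unit-slope tails,
so matching a section to its own histogram is exactly the identity and
matching twice changes at most one gray level.  The classical tissue
mask (intensity range + local-texture floor + morphology at ~1 µm
pixels, enclosed holes filled but re-checked against the intensity
range so debris stays excluded) is a deterministic stand-in behind the
same mask interface that externally produced (e.g. learned) masks use.

## Rough and elastic 3D alignment

Feature detection is injectable; the default is `skimage.feature.SIFT`
with no initial upsampling (EM texture yields plentiful keypoints and
detection is ~4× faster).  Lowe matching keeps a match iff
d₂/d₁ ≥ 1.42 and is deliberately not one-to-one.  Pairwise constrained
affines are evaluated on a fixed hexagonal grid (25 µm production
spacing) as `T(p) − p`; grid points > 60 µm from any inlier keypoint
are invalidated; interior grid points are moved to their Voronoi-cell
centroids before solving.  The per-grid-point z-chain solve, trend
removal and blockwise stitching are described above; the resolved
fields are refit with the zero-shear affine (the full-affine refit
demonstrably carries planted shear; the constrained refit cannot, by
construction).

Fine/ultrafine measurement crops are preprocessed once per section
(whole-image CLAHE + LoG), then cropped — equivalent to per-crop
preprocessing but far cheaper.  Outlier rejection fits a quadratic
affine field (basis 1, x, y, x², xy, y² per axis, minimal sample 6,
seeded RANSAC, tolerance 12 µm production / scaled on fixtures), then
re-admits rejected vectors supported by their neighborhood: a vector is
re-admitted when at least 3 of its 6 most vector-similar neighbors
within the 57 µm diameter agree with it in angle (≤ 25°) and magnitude
(≤ 30 %).  Requiring several independent agreements lets coherent
locally-deviating patches return while isolated gross outliers almost
never find support (thresholds config-exposed; the neighborhood
includes rejected vectors, otherwise no coherent patch could ever
return).  Outliers and unmeasured points are replaced by rigid-MLS
estimates (solver weight 0.5); the affine filter (full-affine fits in
sliding 61 µm windows, center vector replaced by the fit) runs after
replacement — globally affine fields are its fixed points, and border
windows shrink without padding.  The per-grid-point solve weights
neighbors 1.0, 1.0, 0.4, 0.1 for |n| = 1..4 and uses ridge (λ = 0.05)
for the ultrafine pass.  Probe misregistration in the tests and the
acceptance report is the *mean* over probe points.

## Tears

The midline interpolates stitch midpoints (ordered along the tear's
principal axis) and extrapolates linearly to the image border; the
section is bisected along it.  Control sources are interpolated along
each half's own lip through its stitch endpoints, destinations are the
matching arclength positions on the midline, and identity anchors on a
coarse grid beyond 60 px of the midline keep the healing strictly
local: only the band within the anchor distance is warped, the rest of
each half is copied verbatim, so the far field is exactly unchanged.
Healing warps each half separately (rigid MLS assumes local rigidity
and cannot represent the discontinuity).  Output pixels that would
sample the open tear are residual gaps — expected between stitches —
filled from their nearest healed neighbor and reported.

## Export

Fields are densified per pixel by Delaunay-based linear interpolation
(the natural bilinear analog on a triangulated hexagonal grid: exact at
grid points and for globally linear fields) with nearest-neighbor
fallback strictly inside the grid bounding box; exports are cropped to
that box to avoid extrapolation, except between pipeline stages, where
the full rough-bbox frame is kept so all stages share one coordinate
frame.  Blocks tile the output with 8 px overlap, trimmed on assembly;
blocked and unblocked exports are bit-identical.  Intensity resampling
is bilinear (config-switchable to cubic).  Output and source pixel
sizes are independent, so 4 nm exports can be driven by 16 nm-derived
transforms.

## Synthetic fixtures

The phantom texture is band-limited Gaussian noise shaped into
membrane-like ridges plus low-frequency voids imitating cell bodies and
vessels, mildly blurred (σ = 1 px) because real acquisitions are not
pixel-sharp and integer-pixel matching relies on neighboring-pixel
correlation.  Tile fixtures plant: Gaussian positional jitter (σ =
0.5 px — the stage/beam error scale), per-beam linear gradients
(0.8–1.2×), zero-mean integer brightness offsets (±10 gray), blank
tiles, and gross positional outliers.  Overlaps are ~15–25 % of the
(downscaled) tile so the overlap strip keeps enough structure to match;
production overlaps are a smaller fraction of much larger tiles.
Stack fixtures share one phantom across sections with 3 % independent
per-section noise, deformed by per-section rigid/no-shear transforms
(white or z-smoothed parameter series; the coarse-error envelope is
white) and/or smooth random elastic fields (default test magnitude
~30 px, smoothness ~120 px).  Tear fixtures cut along a sinusoidal
near-vertical path and pull the halves apart symmetrically, with
stitch pairs placed exactly on the lips.

What passing these fixtures does *not* show: robustness to real
section-to-section content change (fixtures share one texture, so
matching is easier in z than reality), charging/debris artifact
diversity, focus variation, or production-scale solver conditioning
(thousands of mFOVs, 91-beam layouts, 721-section blocks).  The
fixture scale is chosen so every stage's recovery is measured against
exact planted ground truth in minutes on one CPU; problem sizes used
by the default tests and the acceptance report are: 7-beam mFOVs
(up to 9 per section, 63 tiles), 8–30 sections of 288²–384² px, one
~2.4 k-point measurement grid per elastic pass.

## Known limitations

- Integer-pixel matching bounds every stage's accuracy at ±0.5 px;
  fixtures with fractional planted jitter show ~1 px worst-case tile
  errors, matching the production residual scale.
- Trend removal on short z-chains eats real smooth drift (see above).
- The classical tissue mask is intensity/texture-based and will not
  separate bare resin from low-texture tissue the way a trained model
  can; the mask interface accepts external masks for that reason.
- Tear healing assumes clean tears (no missing tissue at the lips) and
  annotated stitch pairs; tears are healed before any 3D stage, which
  the CLI ordering enforces.
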