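"""Ground-truth fixture generation.

Phantom EM-like textures, sliced and deformed by known transforms, split
into overlapping hexagonal tile layouts with planted acquisition
artifacts (positional jitter, per-beam gradients and brightness offsets,
blank tiles, low-contrast sections, tears).  Every stage of the pipeline
has a recovery test against the planted ground truth, with no external
data.

The texture model is band-limited Gaussian noise shaped into
membrane-like ridges plus low-frequency voids emulating cell bodies —
enough correlatable structure for template matching, plus realistic
low-structure regions that exercise the outlier paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Dataset
from .montage2d import MfovLayout
from .types import RoiSpec, SectionImage, Tile


def phantom_texture(shape, seed=0, ridge_scale_px=6.0, void_scale_px=40.0):
    """EM-like 8-bit phantom: ridged band-limited noise with soft voids."""
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), ridge_scale_px / 3)
    ridges = np.exp(-(noise / (noise.std() + 1e-12)) ** 2 / 0.25)  # membrane-like
    lowf = ndimage.gaussian_filter(rng.standard_normal(shape), void_scale_px / 3)
    voids = lowf > np.quantile(lowf, 0.8)
    img = 0.75 - 0.5 * ridges
    img[voids] = 0.72 + 0.04 * ndimage.gaussian_filter(
        rng.standard_normal(shape), 3)[voids]
    img = np.clip(img + 0.02 * rng.standard_normal(shape), 0, 1)
    # mild optical blur: real acquisitions are not pixel-sharp, and the
    # montage/alignment error model (integer-pixel matching) relies on
    # neighboring-pixel correlation
    img = ndimage.gaussian_filter(img, 1.0)
    return (img * 255).astype(np.uint8)


def smooth_field(shape, seed=0, magnitude_px=10.0, smoothness_px=80.0):
    """Smooth random 2-D displacement field, (H, W, 2) in (x, y) px."""
    rng = np.random.default_rng(seed)
    f = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(shape), smoothness_px)
        for _ in range(2)
    ], axis=-1)
    norm = np.abs(f).max()
    if norm > 0:
        f = f / norm * magnitude_px
    return f


@dataclass
class TileFixtureSpec:
    seed: int = 0
    n_beams: int = 7
    n_mfovs: int = 1
    tile_shape_px: tuple[int, int] = (96, 96)
    pixel_size_nm: float = 16.0
    intra_overlap_nm: float = 16.0 * 16   # ~1-2 um at production scale
    inter_overlap_nm: float = 16.0 * 24
    jitter_px: float = 0.5
    gradient_range: tuple[float, float] = (1.0, 1.0)  # e.g. (0.8, 1.2)
    offset_range_gray: float = 0.0                    # e.g. 10 -> +-10
    blank_fraction: float = 0.0
    outlier_fraction: float = 0.0     # tiles given gross positional errors


@dataclass
class TileFixture:
    tiles: list
    layout: MfovLayout
    true_positions: np.ndarray   # (T, 2) nm tile centers in phantom frame
    phantom: np.ndarray
    phantom_origin_nm: np.ndarray
    beam_gradients: dict          # beam_id -> multiplicative raster
    beam_offsets: dict            # beam_id -> additive gray offset
    blank_tiles: np.ndarray       # bool per tile
    outlier_tiles: np.ndarray     # bool per tile


def generate_tile_fixture(spec: TileFixtureSpec) -> TileFixture:
    """Cut a phantom into a hexagonal tile layout with planted artifacts."""
    rng = np.random.default_rng(spec.seed)
    layout = MfovLayout(spec.tile_shape_px, spec.pixel_size_nm,
                        n_beams=spec.n_beams,
                        intra_overlap_nm=spec.intra_overlap_nm,
                        inter_overlap_nm=spec.inter_overlap_nm)
    beam_pos = layout.beam_positions()
    centers = layout.mfov_centers(spec.n_mfovs)
    nominal = np.concatenate([c + beam_pos for c in centers])  # (T, 2)
    mfov_ids = np.repeat(np.arange(spec.n_mfovs), spec.n_beams)
    beam_ids = np.tile(np.arange(spec.n_beams), spec.n_mfovs)

    px = spec.pixel_size_nm
    h, w = spec.tile_shape_px
    jitter = rng.normal(0, spec.jitter_px * px, nominal.shape)
    true_pos = nominal + jitter

    n_tiles = len(nominal)
    outlier_tiles = rng.random(n_tiles) < spec.outlier_fraction
    if outlier_tiles.any():
        true_pos[outlier_tiles] += rng.uniform(4, 8, (outlier_tiles.sum(), 2)) \
            * px * rng.choice([-1, 1], (outlier_tiles.sum(), 2))
    blank = rng.random(n_tiles) < spec.blank_fraction

    # phantom large enough to cover all tiles with margin
    lo = true_pos.min(0) - np.array([w, h]) * px
    hi = true_pos.max(0) + np.array([w, h]) * px
    shape = (int(np.ceil((hi[1] - lo[1]) / px)), int(np.ceil((hi[0] - lo[0]) / px)))
    phantom = phantom_texture(shape, seed=spec.seed + 1)

    g0, g1 = spec.gradient_range
    gradients, offsets = {}, {}
    yy = np.linspace(0, 1, h)[:, None]
    xx = np.linspace(0, 1, w)[None, :]
    for b in range(spec.n_beams):
        if g0 == g1 == 1.0:
            gradients[b] = np.ones((h, w))
        else:
            t = rng.random(2)
            ramp = t[0] * xx + (1 - t[0]) * yy
            if t[1] > 0.5:
                ramp = 1 - ramp
            gradients[b] = g0 + (g1 - g0) * ramp
        offsets[b] = float(np.round(rng.uniform(-1, 1) * spec.offset_range_gray))
    # planted offsets are relative: force them to zero mean as the
    # correction can only recover relative brightness
    if spec.offset_range_gray > 0:
        mean_off = np.mean(list(offsets.values()))
        offsets = {b: v - mean_off for b, v in offsets.items()}

    tiles = []
    for i in range(n_tiles):
        c0 = int(np.round((true_pos[i, 0] - lo[0]) / px - w / 2))
        r0 = int(np.round((true_pos[i, 1] - lo[1]) / px - h / 2))
        crop = phantom[r0:r0 + h, c0:c0 + w].astype(np.float64)
        if blank[i]:
            crop = np.full((h, w), 128.0)
        else:
            crop = crop * gradients[beam_ids[i]] + offsets[beam_ids[i]]
        tiles.append(Tile(np.clip(np.round(crop), 0, 255).astype(np.uint8),
                          int(mfov_ids[i]), int(beam_ids[i]),
                          nominal[i], px))
    # snap true positions to the integer crop grid actually used
    snapped = np.column_stack([
        (np.round((true_pos[:, 0] - lo[0]) / px - w / 2) + w / 2) * px + lo[0],
        (np.round((true_pos[:, 1] - lo[1]) / px - h / 2) + h / 2) * px + lo[1],
    ])
    return TileFixture(tiles, layout, snapped, phantom, lo,
                       gradients, offsets, blank, outlier_tiles)


def fixture_dataset(fix: TileFixture, section: int = 0) -> Dataset:
    ds = Dataset()
    ds.sections[section] = list(fix.tiles)
    return ds


# ---------------------------------------------------------------------------
# 3D stack fixtures


@dataclass
class StackFixtureSpec:
    seed: int = 0
    n_sections: int = 12
    section_shape_px: tuple[int, int] = (384, 384)
    pixel_size_nm: float = 16.0
    transform_family: str = "rigid"   # "none" | "rigid" | "noshear" | "elastic"
    max_rotation_deg: float = 10.0
    max_translation_px: float = 20.0
    scale_range: tuple[float, float] = (0.97, 1.03)
    shear_range: tuple[float, float] = (0.0, 0.0)
    smooth_z: bool = True             # smooth parameter drift along z vs white
    elastic_magnitude_px: float = 0.0
    elastic_smoothness_px: float = 120.0
    content_noise: float = 0.03       # per-section independent texture noise
    low_contrast_sections: tuple[int, ...] = ()
    contrast_factor: float = 0.5


@dataclass
class StackFixture:
    sections: list                 # SectionImage (deformed, as "acquired")
    reference: np.ndarray          # the undeformed phantom
    transforms: list               # per-section planted AffineTransform2D
                                   # (maps section px -> reference px: the
                                   # section is rendered by sampling the
                                   # reference at T(p))
    elastic_fields: list           # per-section (H, W, 2) dst->src px field or None
    spec: StackFixtureSpec


def generate_stack_fixture(spec: StackFixtureSpec) -> StackFixture:
    """Sections sharing one phantom texture, each deformed by a known
    transform (and optional smooth elastic field) plus mild independent
    noise.  The planted transform maps the section's own pixel
    coordinates to reference coordinates: the section image is rendered
    by sampling the reference at ``T(p)`` (after the elastic field, when
    present, perturbs the lookup), so ``T^{-1}`` re-creates the
    reference from the section.
    """
    from .transforms2d import AffineTransform2D

    rng = np.random.default_rng(spec.seed)
    H, W = spec.section_shape_px
    margin = int(np.ceil(spec.max_translation_px + 0.3 * max(H, W)
                         + spec.elastic_magnitude_px + 8))
    ph_shape = (H + 2 * margin, W + 2 * margin)
    phantom = phantom_texture(ph_shape, seed=spec.seed + 7)

    def series(amplitude):
        """Per-section parameter sequence in [-amplitude, amplitude]."""
        if spec.transform_family == "none" or amplitude == 0:
            return np.zeros(spec.n_sections)
        raw = rng.standard_normal(spec.n_sections)
        if spec.smooth_z and spec.n_sections > 3:
            raw = ndimage.gaussian_filter1d(raw, spec.n_sections / 8.0,
                                            mode="nearest")
        peak = np.abs(raw).max()
        return raw / peak * amplitude if peak > 0 else raw

    def series_range(lo, hi):
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        return mid + series(half)

    center = np.array([W / 2.0, H / 2.0])
    angles = series(spec.max_rotation_deg)
    txs = series(spec.max_translation_px)
    tys = series(spec.max_translation_px)
    sxs = series_range(*spec.scale_range)
    sys_ = series_range(*spec.scale_range)
    shears = series_range(*spec.shear_range)
    sections, transforms, fields = [], [], []
    for k in range(spec.n_sections):
        if spec.transform_family == "none":
            T = AffineTransform2D.identity()
        else:
            T = AffineTransform2D.rotation(angles[k], center=center)
            if spec.transform_family == "noshear":
                S = np.diag([sxs[k], sys_[k]])
                T = T.compose_with(AffineTransform2D(S, center - S @ center))
            if spec.shear_range != (0.0, 0.0):
                Sh = np.array([[1.0, shears[k]], [0.0, 1.0]])
                T = T.compose_with(AffineTransform2D(Sh, center - Sh @ center))
            T = AffineTransform2D(T.linear,
                                  T.translation + [txs[k], tys[k]])
        transforms.append(T)

        fld = None
        if spec.transform_family == "elastic" and spec.elastic_magnitude_px > 0:
            fld = smooth_field((H, W), seed=spec.seed + 100 + k,
                               magnitude_px=spec.elastic_magnitude_px,
                               smoothness_px=spec.elastic_smoothness_px)
        fields.append(fld)

        # sample the section: section pixel p_sec <- phantom at
        # Tinv(p_sec) (+margin); elastic field perturbs the lookup
        yy, xx = np.mgrid[0:H, 0:W]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        if fld is not None:
            pts = pts + fld.reshape(-1, 2)
        src = T.apply(pts) + margin  # into phantom coords
        noise = spec.content_noise * 255 * rng.standard_normal((H, W))
        samp = ndimage.map_coordinates(
            phantom.astype(np.float64),
            [src[:, 1].reshape(H, W), src[:, 0].reshape(H, W)],
            order=1, mode="constant", cval=0.0)
        img = samp + noise
        if k in spec.low_contrast_sections:
            img = (img - 128.0) * spec.contrast_factor + 128.0
        sec = SectionImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                           spec.pixel_size_nm, order_index=k)
        sections.append(sec)

    reference = phantom[margin:margin + H, margin:margin + W]
    return StackFixture(sections, reference, transforms, fields, spec)


def probe_registration(
    recovered_lookup,
    planted_lookup,
    shape_px,
    n_probes: int = 20,
    seed: int = 0,
    border_px: int = 32,
) -> np.ndarray:
    """Misregistration (px) between recovered and planted coordinate
    lookups at random probe points.

    Both lookups map (N, 2) output/aligned pixel coordinates to source
    coordinates; the return value is the per-probe Euclidean difference.
    """
    rng = np.random.default_rng(seed)
    H, W = shape_px
    pts = np.column_stack([
        rng.uniform(border_px, W - border_px, n_probes),
        rng.uniform(border_px, H - border_px, n_probes),
    ])
    a = np.asarray(recovered_lookup(pts), float)
    b = np.asarray(planted_lookup(pts), float)
    return np.linalg.norm(a - b, axis=1)


# ---------------------------------------------------------------------------
# tear fixtures


@dataclass
class TearFixture:
    torn: np.ndarray            # the torn image
    original: np.ndarray
    pairs: np.ndarray           # (K, 4) stitch pairs (ax, ay, bx, by) px
    midline_x: np.ndarray       # true cut x at each row (vertical-ish tear)


def generate_tear_fixture(shape=(256, 256), seed=0, opening_px=12.0,
                          n_stitches=9, curve_px=15.0):
    """Cut a phantom along a near-vertical curved path and pull the two
    halves apart horizontally by ``opening_px``."""
    rng = np.random.default_rng(seed)
    H, W = shape
    img = phantom_texture(shape, seed=seed + 3)
    y = np.arange(H)
    midx = W / 2 + curve_px * np.sin(2 * np.pi * y / H + rng.uniform(0, 2 * np.pi))

    torn = np.zeros((H, W), np.float64)
    half = opening_px / 2.0
    xs = np.arange(W, dtype=float)
    for r in range(H):
        row = img[r].astype(np.float64)
        left = xs <= midx[r]
        # left half shifts -half, right half +half
        torn[r] += np.interp(xs + half, xs[left], row[left], left=0, right=0) \
            * (xs <= midx[r] - half)
        right = xs > midx[r]
        torn[r] += np.interp(xs - half, xs[right], row[right], left=0, right=0) \
            * (xs > midx[r] + half)
    rows = np.linspace(H * 0.08, H * 0.92, n_stitches).astype(int)
    pairs = np.column_stack([
        midx[rows] - half, rows.astype(float),   # point on the left lip
        midx[rows] + half, rows.astype(float),   # the matching right lip
    ])
    return TearFixture(np.clip(np.round(torn), 0, 255).astype(np.uint8),
                       img, pairs, midx)
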