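"""3D coarse and rough alignment.

Coarse alignment re-orients every section by the angle and center of
its acquisition ROI and crops to a shared rough bounding box, leaving
residual errors of up to ~100 um translation and ~15 degrees rotation.
The rough alignment then estimates one constrained affine per section:
scale-invariant features are matched between each section and its
i +- n neighbors (Lowe ratio test, ratio 1.42), pairwise constrained
affines are fitted with RANSAC, the affines are evaluated on a fixed
hexagonal grid to produce vector fields, a per-grid-point z-chain
difference system is solved blockwise (with per-grid-point linear trend
removal), and the resolved per-section fields are refit with zero-shear
affines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree, Voronoi
from skimage.feature import SIFT
from skimage.transform import AffineTransform, warp

from .config import PipelineConfig
from .grids import Comparison, VectorFieldSet, hex_grid
from .lss import DeltaGraph, remove_linear_trend, solve
from .transforms2d import (
    AffineTransform2D,
    PointCorrespondences,
    fit_affine,
    ransac_fit,
)
from .types import RoiSpec, SectionImage

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coarse alignment


def coarse_transform(roi: RoiSpec, bbox, pixel_size_nm: float) -> AffineTransform2D:
    """Transform (section px -> bbox-local px) that rotates by the ROI
    angle about the ROI center and moves the ROI center to the center of
    the rough bounding box.  Output coordinates are local to the bbox
    (its origin is pixel 0,0)."""
    x0, y0, x1, y1 = bbox
    bbox_center_px = np.array([(x1 - x0) / 2.0, (y1 - y0) / 2.0]) / pixel_size_nm
    roi_center_px = roi.center_xy / pixel_size_nm
    rot = AffineTransform2D.rotation(-roi.angle_deg, center=roi_center_px)
    return AffineTransform2D(rot.linear,
                             rot.translation + bbox_center_px - roi_center_px)


def coarse_align(section: SectionImage, roi: RoiSpec, bbox) -> SectionImage:
    """Apply the coarse transform and crop to the rough bounding box."""
    px = section.pixel_size_nm
    h, w = section.image.shape
    if not (0 <= roi.center_xy[0] / px < w and 0 <= roi.center_xy[1] / px < h):
        raise ValueError("ROI center outside the section image")
    T = coarse_transform(roi, bbox, px)
    x0, y0, x1, y1 = bbox
    out_shape = (int(round((y1 - y0) / px)), int(round((x1 - x0) / px)))
    inv = T.inverse()
    sk = AffineTransform(matrix=np.vstack([
        np.column_stack([inv.linear, inv.translation]), [0, 0, 1]]))
    warped = warp(section.image.astype(np.float64), sk, output_shape=out_shape,
                  order=1, mode="constant", cval=0.0)
    out = SectionImage(np.clip(np.round(warped), 0, 255).astype(np.uint8), px,
                       roi=roi, order_index=section.order_index)
    out.coarse = T
    return out


# ---------------------------------------------------------------------------
# features and matching


def detect_features(image: np.ndarray, detector=None):
    """Keypoints (x, y px) and descriptors; the detector is injectable
    and defaults to skimage's SIFT."""
    # no initial upsampling: keypoints are plentiful at EM texture density
    # and detection is ~4x faster than with the doubled base octave
    det = detector if detector is not None else SIFT(upsampling=1)
    try:
        det.detect_and_extract(image)
    except RuntimeError:
        return np.zeros((0, 2)), np.zeros((0, 128))
    kp = det.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return kp, det.descriptors.astype(float)


def match_sections(
    featA, featB, lowe_ratio: float = 1.42
) -> PointCorrespondences:
    """Lowe-ratio matching of descriptor sets.

    A match survives iff distance(second-nearest) / distance(nearest)
    >= ``lowe_ratio``; matches need not be one-to-one.
    """
    kpA, descA = featA
    kpB, descB = featB
    if len(descA) == 0 or len(descB) < 2:
        return PointCorrespondences(np.zeros((0, 2)), np.zeros((0, 2)))
    A = np.asarray(descA, np.float32)
    B = np.asarray(descB, np.float32)
    # squared Euclidean distances via one BLAS product
    d2 = (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * (A @ B.T)
    np.clip(d2, 0, None, out=d2)
    idx1 = np.argmin(d2, axis=1)
    d1 = d2[np.arange(len(A)), idx1]
    d2[np.arange(len(A)), idx1] = np.inf
    dsecond = d2.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.sqrt(dsecond) / np.sqrt(d1)
    keep = (d1 == 0) | (ratio >= lowe_ratio)
    return PointCorrespondences(kpA[keep], kpB[idx1[keep]])


# ---------------------------------------------------------------------------
# pairwise affines


@dataclass
class PairResult:
    i: int
    n: int
    transform: AffineTransform2D | None
    n_matches: int
    flag: str = ""      # "", "too-few-matches", "no-model", "translation"
    inlier_keypoints: np.ndarray | None = None


def neighbor_affines(
    features: list,
    pixel_size_nm: float,
    config: PipelineConfig = PipelineConfig(),
    constraint: str = "rigid",
    n_neighbors: int | None = None,
    seed: int = 0,
) -> list[PairResult]:
    """RANSAC constrained affines for every (i, i+n) pair, n = 1..max.

    The transform maps section i pixel coordinates onto section i+n.
    Pairs with fewer than ``min_feature_matches`` surviving matches, or
    with a fitted translation above ``max_translation_nm``, are flagged
    as bad and carry no transform.
    """
    n_sections = len(features)
    nmax = n_neighbors if n_neighbors is not None else config.rough_n_neighbors
    results = []
    for i in range(n_sections):
        for n in range(1, nmax + 1):
            j = i + n
            if j >= n_sections:
                continue
            corr = match_sections(features[i], features[j], config.lowe_ratio)
            if len(corr) < config.min_feature_matches:
                results.append(PairResult(i, n, None, len(corr), "too-few-matches"))
                continue
            corr_nm = PointCorrespondences(corr.src * pixel_size_nm,
                                           corr.dst * pixel_size_nm)
            model, mask = ransac_fit(
                corr_nm, constraint,
                tolerance_nm=config.rough_ransac_tol_nm,
                min_inliers=config.min_feature_matches,
                max_translation_nm=config.max_translation_nm,
                seed=seed + 1000 * i + n,
            )
            if model is None:
                results.append(PairResult(i, n, None, len(corr), "no-model"))
                continue
            results.append(PairResult(
                i, n, model, int(mask.sum()),
                inlier_keypoints=corr_nm.src[mask]))
    return results


# ---------------------------------------------------------------------------
# vector fields and the rough delta solve


def voronoi_centroids(grid: np.ndarray) -> np.ndarray:
    """Replace each interior grid point by the centroid of its Voronoi
    cell's vertices; border points (open cells) are kept as-is."""
    if len(grid) < 5:
        return grid.copy()
    vor = Voronoi(grid)
    out = grid.copy()
    for p, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if region and -1 not in region:
            out[p] = vor.vertices[region].mean(axis=0)
    return out


def affines_to_fields(
    pairs: list[PairResult],
    bbox,
    config: PipelineConfig = PipelineConfig(),
    use_centroids: bool = True,
) -> VectorFieldSet:
    """Evaluate fitted affines on the fixed hexagonal grid.

    The delta at grid point p is ``T(p) - p``; points farther than the
    keypoint cutoff from any inlier keypoint are invalidated.
    """
    grid = hex_grid(bbox, config.rough_grid_spacing_nm)
    if use_centroids:
        grid = voronoi_centroids(grid)
    fields = VectorFieldSet(grid, spacing_nm=config.rough_grid_spacing_nm)
    for pr in pairs:
        if pr.transform is None:
            fields.comparisons.append(Comparison(
                pr.i, pr.n, np.zeros((len(grid), 2)),
                np.zeros(len(grid), bool)))
            continue
        deltas = pr.transform.apply(grid) - grid
        valid = np.ones(len(grid), bool)
        if pr.inlier_keypoints is not None and len(pr.inlier_keypoints):
            tree = cKDTree(pr.inlier_keypoints)
            d, _ = tree.query(grid)
            valid = d <= config.keypoint_cutoff_nm
        fields.comparisons.append(Comparison(pr.i, pr.n, deltas, valid))
    return fields


def rough_delta_solve(
    fields: VectorFieldSet,
    n_sections: int,
    config: PipelineConfig = PipelineConfig(),
    block_context: int | None = None,
    block_solve: int | None = None,
    detrend: bool = True,
) -> list[np.ndarray]:
    """Per-grid-point z-chain solve of all neighbor deltas, blockwise.

    For each grid point independently the difference system over all
    (i, i+n) deltas is solved; per block and per grid point a linear
    trend (with offset) over z is removed.  Each section's solution is
    taken from the block that solves it.

    Returns one (G, 2) correction field per section: sampling section
    ``i`` at ``p + field_i(p)`` brings the stack into register (the
    field is a destination-to-source lookup; a section whose content is
    displaced by +d resolves to a lookup of about +d, i.e. the rendered
    content moves back by -d).  Grid points with no valid measurement
    anywhere stay 0 and are reported via a warning.
    """
    ctx = block_context or config.rough_block_context
    sol = block_solve or config.rough_block_solve
    G = fields.n_points
    out = [np.zeros((G, 2)) for _ in range(n_sections)]

    blocks = []
    start = 0
    while start < n_sections:
        stop = min(start + sol, n_sections)
        pad = max(0, (ctx - (stop - start)) // 2)
        lo = max(0, start - pad)
        hi = min(n_sections, stop + pad)
        blocks.append((start, stop, lo, hi))
        start = stop

    dropped = 0
    for g in range(G):
        # collect all valid deltas at this grid point
        entries = [(c.i, c.i + c.n, c.deltas[g]) for c in fields.comparisons
                   if c.valid[g]]
        if not entries:
            dropped += 1
            continue
        for (start, stop, lo, hi) in blocks:
            nb = hi - lo
            edges, deltas = [], []
            for i, j, d in entries:
                if lo <= i < hi and lo <= j < hi:
                    edges.append((i - lo, j - lo))
                    deltas.append(d)
            if not edges:
                continue
            # sections not touched by any edge would disconnect the block;
            # solve only the connected range and leave the rest at zero
            try:
                solved = solve(DeltaGraph(nb, edges, np.array(deltas)))
                coords = solved.coords
            except ValueError:
                continue
            if detrend and nb >= 2:
                coords, _, _ = remove_linear_trend(coords, np.arange(nb))
            for s in range(start, stop):
                out[s][g] = coords[s - lo]
    if dropped:
        log.warning("%d grid points had no valid deltas and were dropped",
                    dropped)
    return out


def refit_section_affine(
    grid: np.ndarray,
    resolved_deltas: np.ndarray,
    valid: np.ndarray | None = None,
    constraint: str = "noshear",
) -> AffineTransform2D:
    """Refit one (no-shear) affine to a section's resolved vector field.

    The correspondence is grid -> grid + delta; with fewer than 2 valid
    points the identity is returned with a warning.
    """
    if valid is None:
        valid = np.ones(len(grid), bool)
    if valid.sum() < 2:
        log.warning("fewer than 2 valid grid points; returning identity")
        return AffineTransform2D.identity()
    corr = PointCorrespondences(grid[valid], grid[valid] + resolved_deltas[valid])
    return fit_affine(corr, constraint)


def rough_align(
    sections: list[SectionImage],
    bbox,
    config: PipelineConfig = PipelineConfig(),
    constraint: str = "rigid",
    refit_constraint: str = "noshear",
    detector_factory=None,
    seed: int = 0,
    n_neighbors: int | None = None,
    block_context: int | None = None,
    block_solve: int | None = None,
):
    """Full rough alignment of a coarse-aligned stack.

    Returns ``(per-section AffineTransform2D, pair results, fields)``;
    each transform is a destination-to-source lookup: it maps registered
    rough-frame coordinates to the section's coarse-aligned frame, so a
    section is rendered by sampling it at ``T(p)``.
    """
    px = sections[0].pixel_size_nm
    feats = []
    for s in sections:
        det = detector_factory() if detector_factory else None
        feats.append(detect_features(s.image, det))
    pairs = neighbor_affines(feats, px, config, constraint=constraint,
                             seed=seed, n_neighbors=n_neighbors)
    fields = affines_to_fields(pairs, bbox, config)
    resolved = rough_delta_solve(fields, len(sections), config,
                                 block_context=block_context,
                                 block_solve=block_solve)
    transforms = [refit_section_affine(fields.grid, r,
                                       constraint=refit_constraint)
                  for r in resolved]
    return transforms, pairs, fields
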