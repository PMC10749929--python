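"""Elastic fine and ultrafine alignment.

After the rough (per-section affine) alignment, residual deformations
are local and non-linear.  The fine alignment measures, at fixed
hexagonal grid locations, how far each section must be translated
locally to match each of its i +- n neighbors (rotation-swept template
matching), robustly rejects outlier vectors (quadratic-affine RANSAC
plus a neighborhood similarity re-admission), replaces rejected and
unmeasured vectors with rigid-MLS estimates, optionally smooths the
fields with an affine filter, and reconciles everything per grid point
with the weighted (optionally ridge) difference-system solver.  The
ultrafine alignment repeats the procedure on the fine-aligned stack
with a denser grid, smaller crops and L2 regularization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import imagecorr
from .config import PipelineConfig
from .grids import Comparison, VectorFieldSet, hex_grid
from .lss import DeltaGraph, solve
from .transforms2d import mls_rigid
from .types import RoiSpec

log = logging.getLogger(__name__)


@dataclass
class FineParams:
    """Geometry/solver parameters for one elastic pass (all nm)."""

    grid_spacing_nm: float = 16_000.0
    src_crop_nm: float = 32_000.0     # search image crop (from the neighbor)
    dst_crop_nm: float = 4_800.0      # template crop (from the section)
    n_neighbors: int = 4
    rotation_sweep_deg: float = 15.0
    rotation_step_deg: float = 3.0
    ransac_tol_nm: float = 12_000.0
    reconsider_diameter_nm: float = 57_000.0
    replaced_weight: float = 0.5
    affine_filter_box_nm: float | None = 61_000.0   # None disables
    neighbor_weights: tuple = (1.0, 1.0, 0.4, 0.1)
    l2: float = 0.0
    roi_scale: float = 1.10
    variance_floor: float = 1.0
    readmit_angle_deg: float = 25.0
    readmit_magnitude_frac: float = 0.3
    readmit_k: int = 6
    readmit_min_agree: int = 3

    def __post_init__(self):
        if self.dst_crop_nm >= self.src_crop_nm:
            raise ValueError("template crop must be smaller than search crop")
        if len(self.neighbor_weights) < self.n_neighbors:
            raise ValueError("need one weight per neighbor distance")

    @classmethod
    def fine(cls, config: PipelineConfig = PipelineConfig()) -> "FineParams":
        return cls(
            grid_spacing_nm=config.fine_grid_spacing_nm,
            src_crop_nm=config.fine_src_crop_nm,
            dst_crop_nm=config.fine_dst_crop_nm,
            n_neighbors=config.fine_n_neighbors,
            rotation_sweep_deg=config.rotation_sweep_deg,
            rotation_step_deg=config.rotation_step_deg,
            ransac_tol_nm=config.fine_ransac_tol_nm,
            reconsider_diameter_nm=config.reconsider_diameter_nm,
            replaced_weight=config.replaced_delta_weight,
            affine_filter_box_nm=config.affine_filter_box_nm,
            neighbor_weights=config.neighbor_weights,
            l2=config.fine_l2,
            roi_scale=config.roi_scale,
            variance_floor=config.variance_floor,
        )

    @classmethod
    def ultrafine(cls, config: PipelineConfig = PipelineConfig()) -> "FineParams":
        return cls(
            grid_spacing_nm=config.ultra_grid_spacing_nm,
            src_crop_nm=config.ultra_src_crop_nm,
            dst_crop_nm=config.ultra_dst_crop_nm,
            n_neighbors=config.ultra_n_neighbors,
            rotation_sweep_deg=config.rotation_sweep_deg,
            rotation_step_deg=config.rotation_step_deg,
            ransac_tol_nm=config.fine_ransac_tol_nm,
            reconsider_diameter_nm=config.reconsider_diameter_nm,
            replaced_weight=config.replaced_delta_weight,
            affine_filter_box_nm=None,
            neighbor_weights=config.neighbor_weights[:config.ultra_n_neighbors],
            l2=config.ultra_l2,
            roi_scale=config.roi_scale,
            variance_floor=config.variance_floor,
        )


def make_masked_grid(
    bbox,
    spacing_nm: float,
    roi: RoiSpec | None = None,
    roi_scale: float = 1.10,
    mask: np.ndarray | None = None,
    mask_pixel_nm: float | None = None,
    mask_dilate_px: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal grid over ``bbox`` with active flags.

    A point is active iff it falls inside the ROI scaled by ``roi_scale``
    about its center AND inside a dilated tissue mask (each constraint
    applied only when provided).
    """
    grid = hex_grid(bbox, spacing_nm)
    active = np.ones(len(grid), bool)
    if roi is not None and roi.half_size_nm is not None:
        rel = grid - roi.center_xy
        t = np.deg2rad(roi.angle_deg)
        rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
        rel = rel @ rot.T
        half = roi.half_size_nm * roi_scale
        active &= (np.abs(rel) <= half).all(axis=1)
    if mask is not None:
        from scipy import ndimage
        m = ndimage.binary_dilation(mask.astype(bool),
                                    iterations=max(1, mask_dilate_px))
        px = mask_pixel_nm or 1024.0
        cols = np.clip((grid[:, 0] / px).astype(int), 0, m.shape[1] - 1)
        rows = np.clip((grid[:, 1] / px).astype(int), 0, m.shape[0] - 1)
        active &= m[rows, cols]
    return grid, active


def measure_fine_deltas(
    images: list[np.ndarray],
    grid: np.ndarray,
    active: np.ndarray,
    params: FineParams,
    pixel_size_nm: float = 16.0,
    config: PipelineConfig = PipelineConfig(),
) -> VectorFieldSet:
    """Rotation-swept template-match deltas for all (i, i+-n) pairs.

    For the comparison (i, j): the template is the small crop of section
    i at the grid point, searched inside the larger crop of section j;
    the measured displacement is the local motion of content from i to
    j, matching the difference-system convention ``delta = x_j - x_i``.
    Points whose crops leave the image or lack contrast are invalid.
    """
    px = pixel_size_nm
    n_sections = len(images)
    dst_half = int(round(params.dst_crop_nm / px / 2))
    src_half = int(round(params.src_crop_nm / px / 2))
    angles = imagecorr.sweep_angles(params.rotation_sweep_deg,
                                    params.rotation_step_deg)

    white = []
    for img in images:
        w, ok = imagecorr.preprocess(
            img, px, clahe_clip_limit=config.clahe_clip_limit,
            clahe_tile_size=config.clahe_tile_size,
            log_sigma=config.log_sigma, variance_floor=0.0)
        white.append(w)

    gpx = np.round(grid / px).astype(int)
    fields = VectorFieldSet(grid, spacing_nm=params.grid_spacing_nm,
                            active=active)
    pairs = [(i, n) for i in range(n_sections)
             for n in range(1, params.n_neighbors + 1) if i + n < n_sections]
    for i, n in pairs:
        j = i + n
        deltas = np.zeros((len(grid), 2))
        valid = np.zeros(len(grid), bool)
        peaks = np.zeros(len(grid))
        H, W = images[i].shape
        for k in np.flatnonzero(active):
            cx, cy = gpx[k]
            if (cy - src_half < 0 or cy + src_half > H
                    or cx - src_half < 0 or cx + src_half > W):
                continue
            tpl_raw = images[i][cy - dst_half:cy + dst_half,
                                cx - dst_half:cx + dst_half]
            if tpl_raw.size == 0 or tpl_raw.astype(float).var() < params.variance_floor:
                continue
            tpl = white[i][cy - dst_half:cy + dst_half,
                           cx - dst_half:cx + dst_half]
            src = white[j][cy - src_half:cy + src_half,
                           cx - src_half:cx + src_half]
            m = imagecorr.nxcorr_match_rotated(src, tpl, angles, px)
            if m.valid:
                deltas[k] = m.delta_xy
                valid[k] = True
                peaks[k] = m.peak_value
        fields.comparisons.append(Comparison(i, n, deltas, valid, peak=peaks))
    return fields


# ---------------------------------------------------------------------------
# outlier rejection


_QUAD = ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2))


def _poly_basis(pts: np.ndarray, quadratic: bool = True) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    terms = _QUAD if quadratic else _QUAD[:3]
    return np.column_stack([x ** i * y ** j for i, j in terms])


def detect_outliers(
    grid: np.ndarray,
    deltas: np.ndarray,
    measured: np.ndarray,
    params: FineParams,
    n_active: int | None = None,
    seed: int = 0,
    n_iterations: int = 500,
):
    """RANSAC on a quadratic-affine vector-field model, then re-admission
    of rejected deltas consistent with their most similar neighbors.

    Returns ``(inlier mask, inlier_fraction)``.  The fraction is inliers
    over active grid points.
    """
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(measured)
    if len(idx) == 0:
        return np.zeros(len(grid), bool), 0.0
    scale = np.abs(grid[idx]).max() or 1.0
    P = grid[idx] / scale
    D = deltas[idx]
    quadratic = len(idx) >= 8
    if not quadratic:
        log.warning("too few deltas for the quadratic model; using linear")
    B = _poly_basis(P, quadratic)
    k = B.shape[1]

    best_mask = None
    best_count = -1
    if len(idx) <= k:
        cands = [np.arange(len(idx))]
    else:
        cands = [rng.choice(len(idx), k, replace=False)
                 for _ in range(n_iterations)]
    for sample in cands:
        try:
            coef, *_ = np.linalg.lstsq(B[sample], D[sample], rcond=None)
        except np.linalg.LinAlgError:
            continue
        r = np.linalg.norm(B @ coef - D, axis=1)
        mask = r <= params.ransac_tol_nm
        if mask.sum() > best_count:
            best_count, best_mask = int(mask.sum()), mask
    # refit on inliers
    if best_mask is not None and best_mask.sum() >= k:
        coef, *_ = np.linalg.lstsq(B[best_mask], D[best_mask], rcond=None)
        best_mask = np.linalg.norm(B @ coef - D, axis=1) <= params.ransac_tol_nm

    inlier = np.zeros(len(grid), bool)
    inlier[idx[best_mask]] = True

    # neighborhood re-admission: a rejected delta consistent with the most
    # similar vectors around it (accepted or not — coherent local patches
    # may be jointly rejected by the global model) is re-admitted
    rejected = idx[~best_mask]
    if len(rejected) and len(idx) > 1:
        tree = cKDTree(grid[idx])
        radius = params.reconsider_diameter_nm / 2.0
        for r_i in rejected:
            nbrs = [idx[m] for m in tree.query_ball_point(grid[r_i], radius)
                    if idx[m] != r_i]
            if not nbrs:
                continue
            vecs = deltas[np.array(nbrs)]
            v = deltas[r_i]
            sim = np.linalg.norm(vecs - v, axis=1)
            close = vecs[np.argsort(sim)[:params.readmit_k]]
            nv = np.linalg.norm(v)
            agree = 0
            for ref in close:
                nr = np.linalg.norm(ref)
                mag_ok = abs(nv - nr) <= params.readmit_magnitude_frac \
                    * max(nr, 1e-9) or max(nv, nr) < 0.05 * params.ransac_tol_nm
                if nv > 1e-9 and nr > 1e-9:
                    cosang = np.clip(v @ ref / (nv * nr), -1, 1)
                    ang_ok = np.degrees(np.arccos(cosang)) \
                        <= params.readmit_angle_deg
                else:
                    ang_ok = True
                agree += mag_ok and ang_ok
            # several independently agreeing similar neighbors re-admit;
            # an isolated gross outlier almost never finds that support
            if agree >= min(params.readmit_min_agree, len(close)):
                inlier[r_i] = True

    denom = n_active if n_active else int(measured.sum())
    frac = float(inlier.sum()) / max(denom, 1)
    return inlier, frac


def replace_outliers(
    grid: np.ndarray,
    deltas: np.ndarray,
    inlier: np.ndarray,
    fill: np.ndarray,
    alpha: float = 2.0,
):
    """Fill outlier and unmeasured grid points by rigid-MLS
    interpolation/extrapolation from the inliers.

    ``fill`` marks the points to estimate.  Returns ``(complete deltas,
    replaced mask)``; raises if fewer than 2 inliers exist.
    """
    if inlier.sum() < 2:
        raise ValueError("fewer than 2 inlier deltas; comparison dropped")
    out = deltas.copy()
    targets = fill & ~inlier
    if targets.any():
        mapped = mls_rigid(grid[inlier], grid[inlier] + deltas[inlier],
                           grid[targets], alpha=alpha)
        out[targets] = mapped - grid[targets]
    return out, targets


def affine_filter(
    grid: np.ndarray,
    deltas: np.ndarray,
    box_nm: float,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Replace each delta with the prediction of a full affine fitted to
    the deltas inside the square window centered on it.

    Globally affine fields are fixed points; windows with fewer than 3
    points pass the delta through unchanged.
    """
    if valid is None:
        valid = np.ones(len(grid), bool)
    out = deltas.copy()
    half = box_nm / 2.0
    vidx = np.flatnonzero(valid)
    if len(vidx) < 3:
        return out
    tree = cKDTree(grid[vidx])
    scale = max(np.abs(grid).max(), 1.0)
    for k in range(len(grid)):
        nbrs = tree.query_ball_point(grid[k], half * np.sqrt(2))
        members = [m for m in nbrs
                   if abs(grid[vidx[m], 0] - grid[k, 0]) <= half
                   and abs(grid[vidx[m], 1] - grid[k, 1]) <= half]
        if len(members) < 3:
            continue
        P = grid[vidx[members]] / scale
        B = _poly_basis(P, quadratic=False)
        coef, *_ = np.linalg.lstsq(B, deltas[vidx[members]], rcond=None)
        out[k] = _poly_basis(grid[None, k] / scale, quadratic=False) @ coef
    return out


# ---------------------------------------------------------------------------
# the fine delta solve


def fine_delta_solve(
    fields: VectorFieldSet,
    n_sections: int,
    params: FineParams,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-grid-point weighted (ridge) solve of all neighbor deltas.

    Edge weight = neighbor weight for |n| times ``replaced_weight`` for
    MLS-replaced deltas.  Returns per-section correction fields (sample
    section i at ``p + field_i(p)``) and the array of solved-vector
    magnitudes (nm) across sections and grid points.
    """
    G = fields.n_points
    out = [np.zeros((G, 2)) for _ in range(n_sections)]
    mags = []
    for g in range(G):
        edges, deltas, weights = [], [], []
        for c in fields.comparisons:
            if not c.valid[g]:
                continue
            w = params.neighbor_weights[c.n - 1]
            if c.replaced[g]:
                w *= params.replaced_weight
            edges.append((c.i, c.i + c.n))
            deltas.append(c.deltas[g])
            weights.append(w)
        if not edges:
            continue
        try:
            solved = solve(DeltaGraph(n_sections, edges, np.array(deltas),
                                      np.array(weights)), l2=params.l2,
                           remove_offset=(params.l2 == 0))
        except ValueError:
            continue
        for s in range(n_sections):
            out[s][g] = solved.coords[s]
    for s in range(n_sections):
        mags.append(np.linalg.norm(out[s], axis=1))
    return out, np.array(mags)


def fine_align(
    images: list[np.ndarray],
    params: FineParams,
    pixel_size_nm: float = 16.0,
    config: PipelineConfig = PipelineConfig(),
    rois: list[RoiSpec] | None = None,
    masks: list[np.ndarray] | None = None,
    seed: int = 0,
    bbox=None,
):
    """Full elastic pass over a stack of equally-shaped aligned images.

    Returns ``(per-section correction fields, fields measured,
    inlier_fractions, magnitudes)``.
    """
    px = pixel_size_nm
    H, W = images[0].shape
    if bbox is None:
        pad = params.src_crop_nm / 2.0
        bbox = (pad, pad, W * px - pad, H * px - pad)
    roi = rois[0] if rois else None
    grid, active = make_masked_grid(bbox, params.grid_spacing_nm, roi,
                                    params.roi_scale)
    fields = measure_fine_deltas(images, grid, active, params, px, config)

    inlier_fracs = {}
    for c in fields.comparisons:
        inlier, frac = detect_outliers(grid, c.deltas, c.valid & active,
                                       params, n_active=int(active.sum()),
                                       seed=seed + 17 * c.i + c.n)
        inlier_fracs[(c.i, c.n)] = frac
        try:
            c.deltas, replaced = replace_outliers(grid, c.deltas, inlier,
                                                  active,
                                                  alpha=config.mls_alpha)
        except ValueError:
            log.warning("comparison (%d,+%d) dropped: too few inliers",
                        c.i, c.n)
            c.valid[:] = False
            continue
        c.valid = active.copy()
        c.replaced = replaced
        if params.affine_filter_box_nm:
            c.deltas = affine_filter(grid, c.deltas,
                                     params.affine_filter_box_nm, c.valid)
    solved, mags = fine_delta_solve(fields, len(images), params)
    return solved, fields, inlier_fracs, mags
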