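"""Semi-automated healing of knife-tear artifacts.

A tear splits a section into two pieces pulled apart by up to ~100 um.
Healing starts from manually annotated control-point pairs straddling
the tear ("stitches"): the tear midline is estimated by interpolating
the stitch midpoints and extrapolating the ends to the image border,
the section is bisected along the midline, and each half is warped
separately onto the midline with the rigid moving-least-squares
deformation (deforming the halves separately keeps the discontinuity
away from the MLS model, which assumes local rigidity).  Torn sections
are healed directly after the 2D alignment, before any 3D stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import interp1d

from .transforms2d import mls_rigid

log = logging.getLogger(__name__)


@dataclass
class TearAnnotation:
    """Ordered stitch pairs (A on one side, B on the other), px."""

    pairs_a: np.ndarray   # (K, 2)
    pairs_b: np.ndarray   # (K, 2)

    def __post_init__(self):
        self.pairs_a = np.atleast_2d(np.asarray(self.pairs_a, float))
        self.pairs_b = np.atleast_2d(np.asarray(self.pairs_b, float))
        if self.pairs_a.shape != self.pairs_b.shape or len(self.pairs_a) < 2:
            raise ValueError("need >= 2 matching stitch pairs")

    @classmethod
    def from_table(cls, table: np.ndarray) -> "TearAnnotation":
        table = np.atleast_2d(np.asarray(table, float))
        return cls(table[:, 0:2], table[:, 2:4])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.pairs_a + self.pairs_b) / 2.0


def estimate_midline(annotation: TearAnnotation, shape,
                     samples_per_px: float = 1.0) -> np.ndarray:
    """Polyline through the stitch midpoints, linearly extrapolated at
    both ends to the image border; bisects the image into two regions.

    Returns a dense (M, 2) polyline ordered along the tear.
    """
    H, W = shape
    mid = annotation.midpoints
    # order midpoints along the principal direction of the tear
    d = mid - mid.mean(0)
    axis = np.linalg.svd(d, full_matrices=False)[2][0]
    order = np.argsort(d @ axis)
    mid = mid[order]

    # arclength parameterization with linear end extrapolation
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    fx = interp1d(t, mid[:, 0], kind="linear", fill_value="extrapolate")
    fy = interp1d(t, mid[:, 1], kind="linear", fill_value="extrapolate")

    def border_t(direction):
        # extend until leaving the image, then bisect back to the border
        step = max(H, W)
        lo, hi = 0.0, step
        pt = lambda tt: np.array([fx(tt), fy(tt)]) if direction > 0 else \
            np.array([fx(-tt), fy(-tt)])
        inside = lambda p: (-0.5 <= p[0] <= W - 0.5) and (-0.5 <= p[1] <= H - 0.5)
        while inside(pt(hi)) and hi < 100 * step:
            hi *= 2
        for _ in range(60):
            m = (lo + hi) / 2
            if inside(pt(m)):
                lo = m
            else:
                hi = m
        return hi if direction > 0 else -hi

    t0 = border_t(-1)
    t1 = t[-1] + border_t(+1) - t[-1] if True else t[-1]
    t1 = t[-1] + (border_t(+1) - t[-1])
    n = max(int((t1 - t0) * samples_per_px), 2 * len(mid))
    ts = np.linspace(t0, t1, n)
    return np.column_stack([fx(ts), fy(ts)])


def bisect(shape, midline: np.ndarray) -> np.ndarray:
    """Label the image into two connected regions separated by the
    midline; returns an integer raster with values {1, 2}."""
    H, W = shape
    barrier = np.zeros((H, W), bool)
    # rasterize the polyline densely
    seg = np.diff(midline, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    npts = int(lens.sum() * 3) + len(midline)
    ts = np.linspace(0, 1, npts)
    cum = np.concatenate([[0], np.cumsum(lens)])
    total = cum[-1]
    pos = np.column_stack([
        np.interp(ts * total, cum, midline[:, 0]),
        np.interp(ts * total, cum, midline[:, 1]),
    ])
    r = np.clip(np.round(pos[:, 1]).astype(int), 0, H - 1)
    c = np.clip(np.round(pos[:, 0]).astype(int), 0, W - 1)
    barrier[r, c] = True
    barrier = ndimage.binary_dilation(barrier)
    labels, n = ndimage.label(~barrier)
    if n < 2:
        raise ValueError("midline does not bisect the image")
    if n > 2:
        # keep the two largest regions, assign slivers to the nearest
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.argsort(sizes)[::-1][:2] + 1
        out = np.where(labels == keep[0], 1, np.where(labels == keep[1], 2, 0))
    else:
        out = labels
    # fill barrier/sliver pixels with the nearest labeled region
    missing = out == 0
    if missing.any():
        _, (ri, ci) = ndimage.distance_transform_edt(missing, return_indices=True)
        out[missing] = out[ri[missing], ci[missing]]
    return out


def _interp_along(points: np.ndarray, spacing_px: float) -> np.ndarray:
    """Resample an ordered polyline at ~uniform arclength spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0], np.cumsum(seg)])
    n = max(int(cum[-1] / spacing_px) + 1, 2)
    ts = np.linspace(0, cum[-1], n)
    return np.column_stack([np.interp(ts, cum, points[:, 0]),
                            np.interp(ts, cum, points[:, 1])])


def heal(
    image: np.ndarray,
    annotation: TearAnnotation,
    control_spacing_px: float = 16.0,
    alpha: float = 2.0,
    anchor_distance_px: float = 60.0,
    anchor_spacing_px: float = 48.0,
    invalid_mask: np.ndarray | None = None,
):
    """Close the tear by warping each half onto the midline.

    Control sources are points interpolated independently along each
    half's side of the tear (through the stitch endpoints on that side);
    control destinations are the corresponding interpolated midline
    points (shared arclength parameterization).  Matched identity
    anchors on a coarse grid beyond ``anchor_distance_px`` from the
    midline keep the healing local (far-field pixels stay put).  Each
    half is warped by rigid MLS using a backward map and recomposited
    along the midline.

    ``invalid_mask`` marks pixels that carry no tissue (default: exact
    zeros, i.e. the open tear itself); output pixels that would sample
    invalid content are small residual gaps, filled from their nearest
    healed neighbor and reported in the diagnostics.

    Returns ``(healed image, diagnostics dict)``.
    """
    H, W = image.shape
    if np.allclose(annotation.pairs_a, annotation.pairs_b):
        # zero-opening tear: all controls already sit on the midline
        return image.copy(), {"midline": annotation.midpoints,
                              "halves": None, "covered": np.ones_like(image, bool),
                              "gap_px": 0}
    if invalid_mask is None:
        invalid_mask = image == 0
    midline = estimate_midline(annotation, (H, W))
    halves = bisect((H, W), midline)

    mid = annotation.midpoints
    d = mid - mid.mean(0)
    axis = np.linalg.svd(d, full_matrices=False)[2][0]
    order = np.argsort(d @ axis)

    # decide which stitch side belongs to which half
    a, b = annotation.pairs_a[order], annotation.pairs_b[order]
    def half_of(pts):
        r = np.clip(np.round(pts[:, 1]).astype(int), 0, H - 1)
        c = np.clip(np.round(pts[:, 0]).astype(int), 0, W - 1)
        votes = halves[r, c]
        return int(np.round(votes.mean()))
    side = {half_of(a): a, half_of(b): b}
    if set(side) != {1, 2}:
        raise ValueError("stitch endpoints do not straddle the midline")

    mid_ordered = (a + b) / 2.0
    mid_ctrl = _interp_along(mid_ordered, control_spacing_px)

    # distance of each pixel to the midline (for anchor placement)
    barrier = halves != halves  # all-False
    mid_r = np.clip(np.round(midline[:, 1]).astype(int), 0, H - 1)
    mid_c = np.clip(np.round(midline[:, 0]).astype(int), 0, W - 1)
    barrier[mid_r, mid_c] = True
    dist_to_mid = ndimage.distance_transform_edt(~barrier)

    out = np.zeros((H, W))
    weight = np.zeros((H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    for label in (1, 2):
        # shared arclength parameterization: same count as midline controls
        m = len(mid_ctrl)
        src_pts = _interp_along(side[label], 1.0)
        idx = np.linspace(0, len(src_pts) - 1, m).astype(int)
        src_ctrl = src_pts[idx]
        # identity anchors keep the far field fixed
        step = max(int(anchor_spacing_px), 1)
        ar, ac = np.mgrid[step // 2:H:step, step // 2:W:step]
        keep = (halves[ar, ac] == label) & (dist_to_mid[ar, ac] > anchor_distance_px)
        anchors = np.column_stack([ac[keep], ar[keep]]).astype(float)
        ctrl_dst = np.vstack([mid_ctrl, anchors])
        ctrl_src = np.vstack([src_ctrl, anchors])
        if np.allclose(ctrl_src, ctrl_dst):
            warped = image.astype(np.float64)
            region = halves == label
            out[region] += warped[region]
            weight[region] += 1
            continue
        # warp only the band around the tear; beyond the anchor distance
        # the half is copied verbatim (healing is strictly local)
        band = dist_to_mid <= anchor_distance_px
        pts = np.column_stack([xx[band], yy[band]]).astype(float)
        src_band = mls_rigid(ctrl_dst, ctrl_src, pts, alpha=alpha)
        src_x = xx.astype(float).copy()
        src_y = yy.astype(float).copy()
        src_x[band] = src_band[:, 0]
        src_y[band] = src_band[:, 1]
        warped = ndimage.map_coordinates(
            image.astype(np.float64), [src_y, src_x],
            order=1, mode="constant", cval=0.0)
        bad = ndimage.map_coordinates(
            invalid_mask.astype(np.float64), [src_y, src_x],
            order=1, mode="constant", cval=1.0) > 0.5
        # the warped half's domain: output pixels whose source lies in
        # the half's original region
        sr = np.clip(np.round(src_y).astype(int), 0, H - 1)
        sc = np.clip(np.round(src_x).astype(int), 0, W - 1)
        region = (halves[sr, sc] == label) & ~bad
        out[region & band] += warped[region & band]
        weight[region & band] += 1
        keep = (halves == label) & ~band & ~invalid_mask
        out[keep] += image[keep].astype(np.float64)
        weight[keep] += 1

    filled = weight > 0
    out[filled] /= weight[filled]
    # residual gaps between stitches: fill from the nearest healed pixel
    gaps = ~filled
    if gaps.any() and filled.any():
        _, (ri, ci) = ndimage.distance_transform_edt(gaps, return_indices=True)
        out[gaps] = out[ri[gaps], ci[gaps]]
    healed = np.clip(np.round(out), 0, 255).astype(np.uint8)
    gap_px = int(gaps.sum())
    return healed, {"midline": midline, "halves": halves, "covered": filled,
                    "gap_px": gap_px}
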