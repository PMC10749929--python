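"""Blockwise final rendering via inverse coordinate transforms.

Export starts from output (rough-bbox) pixel coordinates and transforms
them back through the chain stages in reverse order — ultrafine field,
fine field, inverse rough affine, inverse coarse affine — yielding a
destination-to-source remap that is applied with standard image
resampling.  Elastic stages are stored as destination-to-source lookups
(output coordinate p samples the previous stage at ``p + field(p)``),
so "inverting" them at export means direct application in remap order;
only the affine stages are algebraically inverted.

Blocks tile the output with a small overlap (default 8 px) that is
trimmed on assembly, making the blocked export identical to an
unblocked one on interior pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .state import ElasticField, TransformChain

log = logging.getLogger(__name__)


@dataclass
class ExportPlan:
    block_grid: tuple[int, int] = (4, 4)
    block_overlap_px: int = 8
    pixel_size_nm: float = 16.0        # output pixel size
    source_pixel_nm: float | None = None  # source image pixel size
    crop_to_grid_bbox: bool = True
    interpolation_order: int = 1       # bilinear; 3 = cubic

    def __post_init__(self):
        if self.block_overlap_px < 0:
            raise ValueError("overlap must be >= 0")
        if self.source_pixel_nm is None:
            self.source_pixel_nm = self.pixel_size_nm


class FieldInterpolator:
    """Linear (Delaunay) interpolation of a grid vector field, exact at
    grid points and for globally linear fields, with nearest-neighbor
    fallback outside the convex hull (inside the grid bbox only)."""

    def __init__(self, field: ElasticField):
        self.field = field
        grid, deltas = field.grid, field.deltas
        if len(grid) >= 3:
            self._lin = LinearNDInterpolator(grid, deltas)
            self._near = NearestNDInterpolator(grid, deltas)
        else:
            self._lin = None
            self._near = NearestNDInterpolator(grid, deltas)
        self.bbox = (grid[:, 0].min(), grid[:, 1].min(),
                     grid[:, 0].max(), grid[:, 1].max())

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if self._lin is not None:
            out = self._lin(pts)
            bad = ~np.isfinite(out).all(axis=1)
            if bad.any():
                out[bad] = self._near(pts[bad])
        else:
            out = self._near(pts)
        return out


def densify_field(field: ElasticField, origin_nm, shape_px,
                  pixel_size_nm: float) -> np.ndarray:
    """Per-pixel displacement raster for a block.

    The block must lie inside the grid bounding box (exports are cropped
    to it; the field is never extrapolated beyond the hull fallback).
    Returns an (H, W, 2) array of x,y displacements in nm.
    """
    interp = FieldInterpolator(field)
    H, W = shape_px
    x0, y0 = origin_nm
    xs = x0 + (np.arange(W) + 0.0) * pixel_size_nm
    ys = y0 + (np.arange(H) + 0.0) * pixel_size_nm
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    return interp(pts).reshape(H, W, 2)


def invert_chain(chain: TransformChain, section: int, coords_nm: np.ndarray,
                 stages=("ultrafine", "fine", "rough", "coarse")) -> np.ndarray:
    """Map output (rough-bbox) coordinates back to source image space.

    ``coords_nm``: (N, 2).  Elastic fields are applied directly (they
    are destination-to-source lookups); affine stages are inverted.
    """
    pts = np.asarray(coords_nm, float).copy()
    for name in stages:
        stage = getattr(chain, name)
        if not stage:
            continue
        entry = stage[section]
        if name in ("ultrafine", "fine"):
            pts = pts + FieldInterpolator(entry)(pts)
        else:
            pts = entry.inverse().apply(pts)
    return pts


def export_block(
    image: np.ndarray,
    chain: TransformChain,
    section: int,
    origin_nm,
    shape_px,
    plan: ExportPlan,
    stages=("ultrafine", "fine", "rough", "coarse"),
) -> np.ndarray:
    """Render one output block by remapping through the inverted chain.

    Remapped coordinates outside the source image are filled with 0.
    """
    H, W = shape_px
    px = plan.pixel_size_nm
    x0, y0 = origin_nm
    xs = x0 + np.arange(W) * px
    ys = y0 + np.arange(H) * px
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    src = invert_chain(chain, section, pts, stages) / plan.source_pixel_nm
    out = ndimage.map_coordinates(
        image.astype(np.float64),
        [src[:, 1].reshape(H, W), src[:, 0].reshape(H, W)],
        order=plan.interpolation_order, mode="constant", cval=0.0)
    return out


def _grid_bbox(chain: TransformChain, section: int):
    for name in ("ultrafine", "fine"):
        stage = getattr(chain, name)
        if stage:
            g = stage[section].grid
            return (g[:, 0].min(), g[:, 1].min(), g[:, 0].max(), g[:, 1].max())
    return None


def export_section(
    image: np.ndarray,
    chain: TransformChain,
    section: int,
    plan: ExportPlan,
    bbox_nm=None,
    stages=("ultrafine", "fine", "rough", "coarse"),
) -> np.ndarray:
    """Blockwise export of one section; blocks are trimmed to remove the
    overlap and assembled seam-free."""
    px = plan.pixel_size_nm
    if bbox_nm is None:
        bbox_nm = chain.rough_bbox
        if plan.crop_to_grid_bbox:
            gb = _grid_bbox(chain, section)
            if gb is not None:
                bbox_nm = gb
    x0, y0, x1, y1 = bbox_nm
    W = int(np.floor((x1 - x0) / px)) + 1
    H = int(np.floor((y1 - y0) / px)) + 1
    br, bc = plan.block_grid
    ov = plan.block_overlap_px
    out = np.zeros((H, W))
    row_edges = np.linspace(0, H, br + 1).astype(int)
    col_edges = np.linspace(0, W, bc + 1).astype(int)
    for bi in range(br):
        for bj in range(bc):
            r0, r1 = row_edges[bi], row_edges[bi + 1]
            c0, c1 = col_edges[bj], col_edges[bj + 1]
            rr0, cc0 = max(0, r0 - ov), max(0, c0 - ov)
            rr1, cc1 = min(H, r1 + ov), min(W, c1 + ov)
            block = export_block(
                image, chain, section,
                (x0 + cc0 * px, y0 + rr0 * px), (rr1 - rr0, cc1 - cc0),
                plan, stages)
            out[r0:r1, c0:c1] = block[r0 - rr0:r1 - rr0, c0 - cc0:c1 - cc0]
    return out


def export_stack(images, chain, plan, stages=("ultrafine", "fine", "rough", "coarse")):
    """Export all sections; returns a list of float rasters."""
    return [export_section(img, chain, s, plan, stages=stages)
            for s, img in enumerate(images)]
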