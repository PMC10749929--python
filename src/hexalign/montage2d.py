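"""2D section montaging.

Tiles acquired by the multibeam microscope sit on a hexagonal lattice
(91 beams in production; smaller rings for fixtures).  Montaging finds
optimal tile-center translations by template-matching every tile against
its (up to six) lattice neighbors, robustly rejecting outlier matches in
two passes, and solving the resulting difference system with the shared
least-squares solver.  The final mosaic is rendered with feathered
(linear ramp) blending across the overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import imagecorr
from .config import PipelineConfig
from .lss import DeltaGraph, SolvedCoordinates, solve
from .types import SectionImage, Tile

log = logging.getLogger(__name__)

# axial-coordinate offsets of the six hex neighbors
HEX_DIRECTIONS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def hex_ring_count(n_rings: int) -> int:
    """Beams in a centered hexagonal layout with ``n_rings`` rings around
    the center: 1, 7, 19, 37, 61, 91, ..."""
    return 1 + 3 * n_rings * (n_rings + 1)


def hex_axial_coords(n_beams: int) -> np.ndarray:
    """Axial (q, r) coordinates for beams, center first, rings outward.

    ``n_beams`` must be a centered hexagonal number.
    """
    coords = [(0, 0)]
    ring = 1
    while len(coords) < n_beams:
        q, r = ring, 0
        for dq, dr in ((-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)):
            for _ in range(ring):
                coords.append((q, r))
                q, r = q + dq, r + dr
        ring += 1
    if len(coords) != n_beams:
        raise ValueError(f"{n_beams} is not a centered hexagonal number")
    return np.array(coords)


@dataclass
class MfovLayout:
    """Hexagonal beam layout of one mFOV plus the nominal overlaps."""

    tile_shape_px: tuple[int, int]          # (h, w)
    pixel_size_nm: float
    n_beams: int = 91
    intra_overlap_nm: float = 1500.0
    inter_overlap_nm: float = 10_000.0

    def __post_init__(self):
        h, w = self.tile_shape_px
        self.tile_size_nm = np.array([w, h], float) * self.pixel_size_nm
        if self.intra_overlap_nm >= min(self.tile_size_nm):
            raise ValueError("overlap must be smaller than the tile")
        self.axial = hex_axial_coords(self.n_beams)
        # pitch: horizontal tile pitch minus overlap; rows interleave at
        # half-pitch horizontally
        self.dx = self.tile_size_nm[0] - self.intra_overlap_nm
        self.dy = self.tile_size_nm[1] - self.intra_overlap_nm

    def beam_positions(self) -> np.ndarray:
        """Nominal beam-center (x, y) offsets from the mFOV center, nm."""
        q = self.axial[:, 0].astype(float)
        r = self.axial[:, 1].astype(float)
        return np.column_stack([(q + r / 2.0) * self.dx, r * self.dy])

    def extent_nm(self) -> np.ndarray:
        pos = self.beam_positions()
        return pos.max(0) - pos.min(0) + self.tile_size_nm

    def mfov_centers(self, n_mfovs: int) -> np.ndarray:
        """Hexagonally packed mFOV center positions (stage coordinates)."""
        ax = hex_axial_coords(_next_hex_number(n_mfovs))[:n_mfovs]
        ext = self.extent_nm()
        dx = ext[0] - self.inter_overlap_nm
        dy = ext[1] - self.inter_overlap_nm
        q, r = ax[:, 0].astype(float), ax[:, 1].astype(float)
        return np.column_stack([(q + r / 2.0) * dx, r * dy])


def _next_hex_number(n: int) -> int:
    k = 0
    while hex_ring_count(k) < n:
        k += 1
    return hex_ring_count(k)


@dataclass
class TileEdge:
    src: int            # tile index within the section list
    dst: int
    kind: str           # "intra" | "inter"
    direction: tuple    # canonical direction key for median grouping


def build_neighbor_graph(tiles: list[Tile], layout: MfovLayout) -> list[TileEdge]:
    """Edges between hex-adjacent tiles (intra) and nearby tiles of
    adjacent mFOVs (inter).  Each unordered pair appears once."""
    ax_by_beam = {i: tuple(layout.axial[i]) for i in range(layout.n_beams)}
    index = {(t.mfov_id, ax_by_beam[t.beam_id]): i for i, t in enumerate(tiles)}
    edges: list[TileEdge] = []
    for i, t in enumerate(tiles):
        q, r = ax_by_beam[t.beam_id]
        for dq, dr in HEX_DIRECTIONS:
            j = index.get((t.mfov_id, (q + dq, r + dr)))
            if j is not None and i < j:
                edges.append(TileEdge(i, j, "intra", (dq, dr)))
    # inter-mFOV: tiles of different mFOVs whose nominal footprints overlap
    # by at least a few pixels in both axes
    min_ov = 4.0 * layout.pixel_size_nm
    pos = np.array([t.nominal_xy for t in tiles])
    mf = np.array([t.mfov_id for t in tiles])
    span = layout.tile_size_nm - min_ov
    for i in range(len(tiles)):
        d = np.abs(pos - pos[i])
        cand = (d[:, 0] < span[0]) & (d[:, 1] < span[1]) & (mf != mf[i])
        for j in np.flatnonzero(cand):
            if i < j:
                v = pos[j] - pos[i]
                sector = int(np.floor(np.arctan2(v[1], v[0]) / (np.pi / 3))) % 6
                edges.append(TileEdge(i, int(j), "inter", ("inter", sector)))
    return edges


def _quarter_crop(tile: Tile, towards: np.ndarray):
    """The half-by-half quadrant of the tile nearest the neighbor.

    Returns ``(crop, center_offset_px)`` where the offset is the quadrant
    center relative to the tile center in (x, y) pixels.
    """
    h, w = tile.image.shape
    right = towards[0] >= 0
    down = towards[1] >= 0
    r0 = h // 2 if down else 0
    c0 = w // 2 if right else 0
    crop = tile.image[r0:r0 + h // 2, c0:c0 + w // 2]
    off = np.array([c0 + (w // 2) / 2.0 - w / 2.0,
                    r0 + (h // 2) / 2.0 - h / 2.0])
    return crop, off


def measure_deltas(
    tiles: list[Tile],
    edges: list[TileEdge],
    config: PipelineConfig = PipelineConfig(),
) -> DeltaGraph:
    """Measure per-edge tile-center deltas (dst - src, nm) by nxcorr.

    The full destination tile is the search image; the quadrant of the
    source tile nearest the destination is the template.  Edges whose raw
    source crop (or destination tile) has grayscale variance below the
    floor are flagged as outliers immediately.
    """
    px = tiles[0].pixel_size_nm
    pre_kwargs = dict(
        pixel_size_nm=px,
        clahe_clip_limit=config.clahe_clip_limit,
        clahe_tile_size=config.clahe_tile_size,
        log_sigma=config.log_sigma,
        variance_floor=config.variance_floor,
    )
    pre_cache: dict[int, tuple[np.ndarray, bool]] = {}

    def dst_pre(i):
        if i not in pre_cache:
            pre_cache[i] = imagecorr.preprocess(tiles[i].image, **pre_kwargs)
        return pre_cache[i]

    deltas = np.zeros((len(edges), 2))
    outlier = np.zeros(len(edges), bool)
    for k, e in enumerate(edges):
        src, dst = tiles[e.src], tiles[e.dst]
        towards = dst.nominal_xy - src.nominal_xy
        crop, qoff = _quarter_crop(src, towards)
        img, img_ok = dst_pre(e.dst)
        if crop.astype(float).var() < config.variance_floor or not img_ok:
            outlier[k] = True
            deltas[k] = dst.nominal_xy - src.nominal_xy
            continue
        tpl, tpl_ok = imagecorr.preprocess(crop, **pre_kwargs)
        if not tpl_ok:
            outlier[k] = True
            deltas[k] = dst.nominal_xy - src.nominal_xy
            continue
        m = imagecorr.nxcorr_match(img, tpl, pixel_size_nm=px, mode="full")
        if not m.valid:
            outlier[k] = True
            deltas[k] = dst.nominal_xy - src.nominal_xy
            continue
        # template center found at dst_center + m.delta; the source center
        # therefore sits at dst_center + m.delta - qoff, so
        # (dst - src) center difference is qoff*px - m.delta
        deltas[k] = qoff * px - m.delta_xy
    return DeltaGraph(len(tiles), [(e.src, e.dst) for e in edges], deltas,
                      outlier=outlier)


def outlier_two_pass(
    graph: DeltaGraph,
    edges: list[TileEdge],
    tiles: list[Tile],
    config: PipelineConfig = PipelineConfig(),
) -> DeltaGraph:
    """Two-pass outlier detection with per-direction median replacement.

    Pass 1 flags deltas outside box tolerances around the acquisition-
    expected delta; medians per neighbor direction are computed over the
    survivors; pass 2 flags deltas outside the (much tighter) box around
    the median.  All flagged edges get the direction median as their
    replacement delta and are down-weighted in the solve.
    """
    expected = np.array([tiles[e.dst].nominal_xy - tiles[e.src].nominal_xy
                         for e in edges])
    intra = np.array([e.kind == "intra" for e in edges])
    tol1 = np.where(intra[:, None], config.intra_tol_pass1_nm,
                    config.inter_tol_pass1_nm)
    tol2 = np.where(intra[:, None], config.intra_tol_pass2_nm,
                    config.inter_tol_pass2_nm)

    flagged = graph.outlier.copy()
    dev1 = np.abs(graph.deltas - expected)
    flagged |= (dev1 > tol1).any(axis=1)

    # per-direction medians over pass-1 survivors
    keys = [(e.kind,) + tuple(e.direction) for e in edges]
    medians: dict[tuple, np.ndarray] = {}
    for key in set(keys):
        sel = np.array([k == key for k in keys]) & ~flagged
        if sel.any():
            medians[key] = np.median(graph.deltas[sel], axis=0)

    def replacement(k):
        med = medians.get(keys[k])
        if med is None:
            log.warning("no surviving deltas for direction %s; using nominal",
                        keys[k])
            return expected[k]
        return med

    meds = np.array([replacement(k) for k in range(len(edges))])
    flagged |= (np.abs(graph.deltas - meds) > tol2).any(axis=1)

    deltas = np.where(flagged[:, None], meds, graph.deltas)
    weights = np.where(flagged, config.replaced_edge_weight, 1.0)
    return DeltaGraph(graph.n_nodes, graph.edges, deltas, weights,
                      outlier=flagged, replaced=flagged)


def solve_section(graph: DeltaGraph, tiles: list[Tile]) -> SolvedCoordinates:
    """Solve tile positions; the solution is re-anchored so its mean
    equals the mean nominal position (the removed offset is reported)."""
    solved = solve(graph, l2=0.0)
    anchor = np.mean([t.nominal_xy for t in tiles], axis=0)
    solved.coords = solved.coords + anchor
    return solved


@dataclass
class FeatherSpec:
    intra_nm: float = 500.0
    inter_nm: float = 3000.0


def _tile_weight(tile: Tile, edges_present: dict, feather: FeatherSpec) -> np.ndarray:
    """Linear edge ramps; sides facing a same-mFOV neighbor use the intra
    ramp, outward-facing sides the inter ramp."""
    h, w = tile.image.shape
    px = tile.pixel_size_nm
    y = np.arange(h)[:, None] + 0.5
    x = np.arange(w)[None, :] + 0.5
    ramps = {side: (feather.intra_nm if edges_present.get(side, False)
                    else feather.inter_nm) / px
             for side in ("left", "right", "top", "bottom")}
    wx = np.minimum(x / max(ramps["left"], 1e-6),
                    (w - x) / max(ramps["right"], 1e-6))
    wy = np.minimum(y / max(ramps["top"], 1e-6),
                    (h - y) / max(ramps["bottom"], 1e-6))
    return np.clip(np.minimum(wx, wy), 1e-6, 1.0) * np.ones((h, w))


def render_montage(
    tiles: list[Tile],
    coords: np.ndarray,
    corrections=None,
    feather: FeatherSpec = FeatherSpec(),
    edges: list[TileEdge] | None = None,
) -> SectionImage:
    """Render the feathered mosaic at the tiles' pixel size.

    ``coords`` are solved tile-center positions in nm.  Blend weights are
    normalized per output pixel (partition of unity), so single-coverage
    pixels equal the corrected tile exactly.
    """
    px = tiles[0].pixel_size_nm
    coords = np.asarray(coords, float)
    h, w = tiles[0].image.shape
    half = np.array([w, h]) / 2.0
    lo = (coords - half * px).min(axis=0)
    hi = (coords + half * px).max(axis=0)
    origin = lo
    W = int(np.ceil((hi[0] - lo[0]) / px))
    H = int(np.ceil((hi[1] - lo[1]) / px))
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))

    # which sides have same-mFOV neighbors (for ramp selection)
    sides: list[dict] = [dict() for _ in tiles]
    if edges is not None:
        for e in edges:
            if e.kind != "intra":
                continue
            v = coords[e.dst] - coords[e.src]
            for idx, vec in ((e.src, v), (e.dst, -v)):
                if abs(vec[0]) >= abs(vec[1]):
                    sides[idx]["right" if vec[0] > 0 else "left"] = True
                else:
                    sides[idx]["bottom" if vec[1] > 0 else "top"] = True

    for i, tile in enumerate(tiles):
        img = tile.image.astype(np.float64)
        if corrections is not None:
            img = corrections.apply(tile, img)
        wgt = _tile_weight(tile, sides[i], feather)
        c0 = int(np.round((coords[i, 0] - half[0] * px - origin[0]) / px))
        r0 = int(np.round((coords[i, 1] - half[1] * px - origin[1]) / px))
        r1, c1 = min(r0 + h, H), min(c0 + w, W)
        rr0, cc0 = max(r0, 0), max(c0, 0)
        tr0, tc0 = rr0 - r0, cc0 - c0
        acc[rr0:r1, cc0:c1] += (img * wgt)[tr0:tr0 + r1 - rr0, tc0:tc0 + c1 - cc0]
        wacc[rr0:r1, cc0:c1] += wgt[tr0:tr0 + r1 - rr0, tc0:tc0 + c1 - cc0]

    out = np.zeros((H, W))
    np.divide(acc, wacc, out=out, where=wacc > 0)
    img8 = np.clip(np.round(out), 0, 255).astype(np.uint8)
    section = SectionImage(img8, px)
    section.origin_nm = origin  # top-left pixel corner in section nm frame
    section.coverage = wacc > 0
    return section


def montage_section(
    tiles: list[Tile],
    layout: MfovLayout,
    config: PipelineConfig = PipelineConfig(),
    corrections=None,
):
    """Full 2D pipeline for one section: graph, deltas, outliers, solve,
    render.  Returns ``(section_image, solved, graph, edges)``."""
    edges = build_neighbor_graph(tiles, layout)
    graph = measure_deltas(tiles, edges, config)
    graph = outlier_two_pass(graph, edges, tiles, config)
    solved = solve_section(graph, tiles)
    feather = FeatherSpec(config.intra_feather_nm, config.inter_feather_nm)
    section = render_montage(tiles, solved.coords, corrections, feather, edges)
    return section, solved, graph, edges
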