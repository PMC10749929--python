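"""Two-pass per-beam gradient and brightness correction, plus the
sub-tile histogram-shift refinement.

Multibeam acquisition leaves a repeating per-beam pattern of intra-tile
brightness gradients and inter-tile brightness offsets.  Pass one
averages, for every beam position, all inlier tiles of a section and
derives a multiplicative gradient correction (box-filtered mean tile
divided by its mode).  Pass two repeats the averaging on the gradient-
corrected tiles and derives an additive per-beam offset (tile mode minus
overall mode).  A final refinement compares 256-bin sub-tile histograms
pairwise by ZNCC over histogram lag, solves per-sub-tile offsets with
the shared difference-system solver (top-n neighbor edges plus minimum
spanning tree edges for connectivity), and fits a smooth 2D polynomial
brightness surface per tile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree

from .config import PipelineConfig
from .lss import DeltaGraph, solve
from .types import Tile

log = logging.getLogger(__name__)


def image_mode(img: np.ndarray, bins: int = 256) -> int:
    """Histogram mode; ties break toward the lower intensity."""
    h = np.bincount(np.clip(np.round(img).astype(int), 0, bins - 1).ravel(),
                    minlength=bins)
    return int(np.argmax(h))


@dataclass
class BeamCorrection:
    """Correction factors applied during montaging.

    corrected = tile / gradient_scale[beam] - brightness_offset[beam]
                - polynomial surface(tile)
    """

    gradient_scale: dict = field(default_factory=dict)   # beam -> raster
    brightness_offset: dict = field(default_factory=dict)  # beam -> float
    tile_surface: dict = field(default_factory=dict)     # tile index -> raster

    def apply(self, tile: Tile, img: np.ndarray, tile_index: int | None = None
              ) -> np.ndarray:
        out = np.asarray(img, np.float64)
        g = self.gradient_scale.get(tile.beam_id)
        if g is not None:
            out = out / g
        off = self.brightness_offset.get(tile.beam_id)
        if off is not None:
            out = out - off
        if tile_index is None:
            tile_index = getattr(tile, "_index", None)
        if tile_index is not None and tile_index in self.tile_surface:
            out = out - self.tile_surface[tile_index]
        return out


@dataclass
class RejectionReport:
    accepted: np.ndarray
    reasons: list


def _section_mode_range(tiles, quantiles, bins=256, fence=1.5):
    """Inlier intensity range from the overall section histogram.

    Tukey fences around the central quantiles: robust even when
    saturated/background artifact pixels make up several percent of the
    section (plain tail quantiles would then include the artifact)."""
    counts = np.zeros(bins)
    for t in tiles:
        counts += np.bincount(t.ravel(), minlength=bins)[:bins]
    cdf = np.cumsum(counts) / counts.sum()
    q_lo = int(np.searchsorted(cdf, quantiles[0]))
    q_hi = int(np.searchsorted(cdf, quantiles[1]))
    iqr = max(q_hi - q_lo, 1)
    lo = max(0, int(q_lo - fence * iqr))
    hi = min(bins - 1, int(q_hi + fence * iqr))
    return lo, hi


def average_beam_tiles(
    tiles: list[Tile],
    config: PipelineConfig = PipelineConfig(),
    images: list[np.ndarray] | None = None,
) -> tuple[dict, RejectionReport]:
    """Mean tile per beam position over inlier tiles.

    Tiles are rejected when their mode falls outside the range derived
    from the overall section histogram (configurable quantiles), or when
    a connected component of out-of-range pixels covers more than the
    configured fraction (default 20%) of the tile.
    """
    if images is None:
        images = [t.image for t in tiles]
    lo, hi = _section_mode_range(images, config.reject_quantiles,
                                 config.histogram_bins)
    accepted = np.ones(len(tiles), bool)
    reasons = [None] * len(tiles)
    for i, img in enumerate(images):
        m = image_mode(img, config.histogram_bins)
        if not (lo <= m <= hi):
            accepted[i] = False
            reasons[i] = f"mode {m} outside [{lo}, {hi}]"
            continue
        out_of_range = (img < lo) | (img > hi)
        if out_of_range.any():
            labels, n = ndimage.label(out_of_range)
            if n:
                largest = np.bincount(labels.ravel())[1:].max()
                if largest > config.large_component_fraction * img.size:
                    accepted[i] = False
                    reasons[i] = (
                        f"component of {largest} out-of-range px "
                        f"(> {config.large_component_fraction:.0%})"
                    )

    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for i, t in enumerate(tiles):
        if not accepted[i]:
            continue
        sums[t.beam_id] = sums.get(t.beam_id, 0) + images[i].astype(np.float64)
        counts[t.beam_id] = counts.get(t.beam_id, 0) + 1
    means = {b: sums[b] / counts[b] for b in sums}
    all_beams = {t.beam_id for t in tiles}
    for b in all_beams - set(means):
        log.warning("beam %d has no inlier tiles; correction falls back to identity", b)
    return means, RejectionReport(accepted, reasons)


def gradient_pass(
    mean_tiles: dict,
    pixel_size_nm: float,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Gradient scale raster per beam: box-filtered mean tile divided by
    its mode.  Dividing tiles by the raster flattens the planted gradient."""
    box = max(1, int(round(config.gradient_box_nm / pixel_size_nm)))
    scales = {}
    for b, mt in mean_tiles.items():
        filt = ndimage.uniform_filter(np.asarray(mt, np.float64), size=box,
                                      mode="nearest")
        mode = image_mode(filt, config.histogram_bins)
        if mode == 0:
            raise ValueError(f"beam {b}: zero mode, cannot form gradient scale")
        scales[b] = filt / mode
    return scales


def brightness_pass(mean_tiles: dict, config: PipelineConfig = PipelineConfig()
                    ) -> dict:
    """Integer brightness offset per beam: mean-tile mode minus the
    overall mode over beams.  Offsets are re-centered to zero mean."""
    if not mean_tiles:
        return {}
    modes = {b: image_mode(mt, config.histogram_bins)
             for b, mt in mean_tiles.items()}
    stacked = np.concatenate([np.asarray(mt).ravel() for mt in mean_tiles.values()])
    overall = image_mode(stacked, config.histogram_bins)
    offsets = {b: float(m - overall) for b, m in modes.items()}
    mean_off = np.mean(list(offsets.values()))
    return {b: v - mean_off for b, v in offsets.items()}


# ---------------------------------------------------------------------------
# sub-tile histogram refinement


def _subtile_histograms(images, grid, bins):
    """Normalized 256-bin histograms for each sub-tile of each tile.

    Returns (hists (S, bins), owner tile index (S,), sub-tile center
    fractional position (S, 2))."""
    gy, gx = grid
    hists, owner, pos = [], [], []
    for ti, img in enumerate(images):
        h, w = img.shape
        for iy in range(gy):
            for ix in range(gx):
                sub = img[iy * h // gy:(iy + 1) * h // gy,
                          ix * w // gx:(ix + 1) * w // gx]
                hh = np.bincount(np.clip(sub.ravel().astype(int), 0, bins - 1),
                                 minlength=bins).astype(np.float64)
                hists.append(hh / max(hh.sum(), 1))
                owner.append(ti)
                pos.append(((ix + 0.5) / gx, (iy + 0.5) / gy))
    return np.array(hists), np.array(owner), np.array(pos)


def _hist_zncc_lag(h1: np.ndarray, h2: np.ndarray, max_lag: int):
    """Best ZNCC between two histograms over integer lags.

    Returns ``(distance, lag)``; a positive lag means ``h2`` is shifted
    toward higher intensities relative to ``h1``, i.e. a brightness
    offset of ``+lag`` gray levels.  Distance is ``1 - peak ZNCC``.
    """
    a = h1 - h1.mean()
    b = h2 - h2.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 2.0, 0
    corr = np.correlate(b / nb, a / na, mode="full")  # lag of b relative to a
    lags = np.arange(-len(a) + 1, len(a))
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    k = int(np.argmax(corr))
    return float(1.0 - corr[k]), int(lags[k])


def subtile_histogram_refine(
    tiles: list[Tile],
    config: PipelineConfig = PipelineConfig(),
    images: list[np.ndarray] | None = None,
    max_lag: int = 64,
    rng=None,
) -> dict:
    """Per-tile smooth polynomial brightness surfaces from the histogram
    shift LSS.

    Sub-tile histograms are compared pairwise by ZNCC over lag; the
    adjacency is the union of each sub-tile's top-n best matches and the
    minimum spanning tree of the full correlation-distance graph (which
    guarantees one connected component).  The difference system over the
    best-match lags yields per-sub-tile brightness offsets (mean
    removed); per tile, the offsets of its sub-tile grid are fit with a
    2D polynomial surface evaluated at full tile resolution.  Sections
    with more than ``subtile_group_size`` sub-tiles are solved in
    randomized independent groups.
    """
    if images is None:
        images = [t.image.astype(np.float64) for t in tiles]
    bins = config.histogram_bins
    hists, owner, rel_pos = _subtile_histograms(images, config.subtile_grid, bins)
    n = len(hists)
    if n < 2:
        raise ValueError("need at least 2 sub-tiles")
    rng = np.random.default_rng(rng)

    groups = [np.arange(n)]
    if n > config.subtile_group_size:
        perm = rng.permutation(n)
        groups = [perm[i:i + config.subtile_group_size]
                  for i in range(0, n, config.subtile_group_size)]

    offsets = np.zeros(n)
    for members in groups:
        m = len(members)
        dist = np.zeros((m, m))
        lag = np.zeros((m, m), int)
        for a in range(m):
            for b in range(a + 1, m):
                d, l = _hist_zncc_lag(hists[members[a]], hists[members[b]], max_lag)
                dist[a, b] = dist[b, a] = d
                lag[a, b] = l
                lag[b, a] = -l
        # top-n neighbors per sub-tile
        edges = set()
        top = min(config.histogram_top_n, m - 1)
        for a in range(m):
            order = np.argsort(dist[a] + np.eye(m)[a] * 1e9)
            for b in order[:top]:
                edges.add((min(a, b), max(a, b)))
        # MST edges guarantee a single component
        mst = minimum_spanning_tree(sp.csr_matrix(dist + 1e-12))
        for a, b in zip(*mst.nonzero()):
            edges.add((min(a, b), max(a, b)))
        edges = sorted(edges)
        deltas = np.array([[lag[a, b], 0.0] for a, b in edges])
        g = DeltaGraph(m, edges, deltas)
        sol = solve(g, l2=0.0)
        offsets[members] = sol.coords[:, 0]

    offsets -= offsets.mean()

    # fit per-tile polynomial surfaces on the sub-tile offset grids
    surfaces = {}
    order = config.surface_order
    terms = [(i, j) for i in range(order + 1) for j in range(order + 1)
             if i + j <= order]
    for ti, img in enumerate(images):
        sel = owner == ti
        p = rel_pos[sel]
        v = offsets[sel]
        A = np.column_stack([p[:, 0] ** i * p[:, 1] ** j for i, j in terms])
        coef = np.linalg.lstsq(A, v, rcond=None)[0]
        h, w = img.shape
        X = (np.arange(w) + 0.5) / w
        Y = (np.arange(h) + 0.5) / h
        XX, YY = np.meshgrid(X, Y)
        surf = sum(c * XX ** i * YY ** j for c, (i, j) in zip(coef, terms))
        surfaces[ti] = surf
    return {"offsets": offsets, "owner": owner, "surfaces": surfaces}


def compute_corrections(
    tiles: list[Tile],
    config: PipelineConfig = PipelineConfig(),
    refine: bool = True,
    rng=None,
) -> BeamCorrection:
    """Full correction stack for one section: gradient pass, brightness
    pass on the gradient-corrected tiles, then the sub-tile refinement."""
    px = tiles[0].pixel_size_nm
    means1, _ = average_beam_tiles(tiles, config)
    grads = gradient_pass(means1, px, config) if means1 else {}

    corrected = []
    for t in tiles:
        img = t.image.astype(np.float64)
        if t.beam_id in grads:
            img = img / grads[t.beam_id]
        corrected.append(np.clip(img, 0, 255))
    means2, _ = average_beam_tiles(tiles, config, images=[c.astype(np.uint8)
                                                          for c in corrected])
    offs = brightness_pass(means2, config)

    corr = BeamCorrection(gradient_scale=grads, brightness_offset=offs)
    if refine:
        imgs2 = []
        for t, img in zip(tiles, corrected):
            off = offs.get(t.beam_id, 0.0)
            imgs2.append(np.clip(img - off, 0, 255))
        result = subtile_histogram_refine(tiles, config, images=imgs2, rng=rng)
        corr.tile_surface = result["surfaces"]
    for i, t in enumerate(tiles):
        t._index = i  # lets render_montage find the per-tile surface
    return corr
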