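"""3D brightness/contrast balancing across sections.

Section thickness variation changes the dynamic range of individual
section images, so every section is histogram-matched to a manually
selected high-contrast template section.  Non-tissue areas (bare resin,
wafer substrate, debris) skew histograms, so only pixels inside a
tissue mask are counted.  The mask provider is pluggable: masks may be
produced externally (e.g. by a learned model) or by the classical
threshold/morphology provider implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.transform import resize

from .types import SectionImage


@dataclass
class TissueMask:
    mask: np.ndarray          # binary, coarse pixel size
    pixel_size_nm: float
    provenance: str = "classical"   # "manual" | "classical" | "learned"

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def _drop_small(binary: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(binary)
    if not n:
        return binary
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def classical_mask(
    section: SectionImage,
    mask_pixel_nm: float = 1024.0,
    intensity_range: tuple[float, float] = (20.0, 235.0),
    texture_floor: float = 4.0,
    min_object_px: int = 16,
    final_dilate_px: int = 1,
) -> TissueMask:
    """Deterministic tissue mask from intensity/texture thresholds plus
    morphological cleanup, at a coarse pixel size (default 1,024 nm).

    Tissue is taken to be pixels inside the plausible intensity range
    whose local grayscale variation exceeds ``texture_floor`` (bare
    resin, wafer background and saturated debris are flat or
    out-of-range).
    """
    img = section.image.astype(np.float64)
    factor = mask_pixel_nm / section.pixel_size_nm
    out_shape = (max(1, int(round(img.shape[0] / factor))),
                 max(1, int(round(img.shape[1] / factor))))
    texture = ndimage.generic_filter(img, np.std, size=5) \
        if img.size < 64 * 64 else ndimage.uniform_filter(
            img ** 2, 5) - ndimage.uniform_filter(img, 5) ** 2
    texture = np.sqrt(np.clip(texture, 0, None))
    lo, hi = intensity_range
    tissue = (img >= lo) & (img <= hi) & (texture >= texture_floor)
    coarse = resize(tissue.astype(np.float64), out_shape, order=1,
                    anti_aliasing=False) > 0.5
    coarse = ndimage.binary_closing(coarse, structure=morphology.disk(2))
    coarse = _drop_small(coarse, min_object_px)          # specks
    # low-texture regions fully enclosed by tissue (cell bodies, vessels)
    # are tissue; only open background stays out
    coarse = ndimage.binary_fill_holes(coarse)
    # enclosed fills must still be intensity-plausible: bright debris and
    # saturated charging stay excluded even when surrounded by tissue
    coarse_img = resize(img, out_shape, order=1, anti_aliasing=True)
    coarse &= (coarse_img >= lo) & (coarse_img <= hi)
    if final_dilate_px and coarse.any():
        # the texture filter erodes the tissue border; grow it back
        coarse = ndimage.binary_dilation(coarse, iterations=final_dilate_px)
    m = TissueMask(coarse, mask_pixel_nm)
    if m.empty:
        import logging
        logging.getLogger(__name__).warning("classical mask is empty")
    return m


def _mask_at_image_scale(section: SectionImage, mask: TissueMask) -> np.ndarray:
    if mask.mask.shape == section.image.shape:
        return mask.mask.astype(bool)
    return resize(mask.mask.astype(np.float64), section.image.shape,
                  order=0, anti_aliasing=False) > 0.5


def masked_histogram(section: SectionImage, mask: TissueMask,
                     bins: int = 256) -> np.ndarray:
    """256-bin histogram over tissue pixels only."""
    m = _mask_at_image_scale(section, mask)
    if not m.any():
        raise ValueError("empty tissue mask")
    vals = section.image[m]
    return np.bincount(vals.ravel(), minlength=bins)[:bins]


def _matching_lut(source_hist: np.ndarray, template_hist: np.ndarray) -> np.ndarray:
    """Monotone gray-level mapping from masked-CDF inversion.

    Each source level maps to the template level at the same CDF
    midpoint (ties broken by midpoint), which keeps the mapping monotone
    non-decreasing.
    """
    s = np.asarray(source_hist, np.float64)
    t = np.asarray(template_hist, np.float64)
    if (s > 0).sum() < 2 or (t > 0).sum() < 2:
        raise ValueError("degenerate (single-bin) histogram")
    s_cdf = np.cumsum(s) / s.sum()
    # midpoint CDF: probability mass strictly below the level plus half
    # the level's own mass — symmetric, so self-matching is the identity
    s_mid = s_cdf - s / s.sum() / 2.0
    t_cdf = np.cumsum(t) / t.sum()
    t_mid = t_cdf - t / t.sum() / 2.0
    levels = np.arange(len(s), dtype=np.float64)
    nzs, nzt = s > 0, t > 0
    # map populated source levels through the template CDF; unpopulated
    # levels (absent inside the mask but possibly present outside it) are
    # filled by monotone interpolation over the gray levels themselves
    mapped = np.interp(s_mid[nzs], t_mid[nzt], levels[nzt])
    lut = np.interp(levels, levels[nzs], mapped)
    # tails outside the populated range follow unit slope so levels that
    # only occur outside the mask keep their relative spacing (and the
    # self-match stays an exact identity)
    first, last = np.flatnonzero(nzs)[[0, -1]]
    below, above = levels < first, levels > last
    lut[below] = np.clip(mapped[0] - (first - levels[below]), 0, None)
    lut[above] = np.clip(mapped[-1] + (levels[above] - last), None, len(s) - 1)
    lut = np.maximum.accumulate(lut)
    return np.clip(np.round(lut), 0, len(s) - 1).astype(np.uint8)


def match_to_template(
    section: SectionImage,
    mask: TissueMask,
    template_hist: np.ndarray,
) -> SectionImage:
    """Histogram-match the whole section to the template histogram,
    with the mapping computed from tissue pixels only."""
    hist = masked_histogram(section, mask, bins=len(template_hist))
    lut = _matching_lut(hist, template_hist)
    out = SectionImage(lut[section.image], section.pixel_size_nm,
                       roi=section.roi, tissue_mask=section.tissue_mask,
                       mask_pixel_nm=section.mask_pixel_nm,
                       order_index=section.order_index)
    return out


def balance_stack(
    sections: list[SectionImage],
    masks: list[TissueMask],
    template_index: int,
) -> list[SectionImage]:
    """Match every section to the histogram of the template section."""
    template_hist = masked_histogram(sections[template_index],
                                     masks[template_index])
    return [match_to_template(s, m, template_hist)
            for s, m in zip(sections, masks)]
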