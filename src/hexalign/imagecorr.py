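"""Image preprocessing and normalized cross-correlation template matching.

The preprocessing chain applied before every template match:

1. contrast normalization with CLAHE (clip limit 30 in the 0-255
   convention, tile size 32 x 32 at a 16 nm pixel size),
2. conversion to float,
3. whitening with a Laplacian-of-Gaussian filter (sigma 4 px at 16 nm),
4. zero-mean / unit-energy normalization (subtract the mean, divide by
   the standard deviation scaled by sqrt(pixel count)), i.e. ZNCC
   normalization.

CLAHE tile size and LoG sigma scale inversely with pixel size so the
filters act at a fixed physical scale.

Correlation surfaces are computed in the frequency domain with spatial
normalization from image integrals (via :func:`skimage.feature.match_template`,
which implements that construction).  Peak localization is integer-pixel;
ties are broken toward the lowest row-major index.

Center convention: the zero-delta template position is the one whose
center sits at ``((H_img - H_tpl) // 2, (W_img - W_tpl) // 2)`` in
valid-mode surface coordinates, i.e. the template centered in the image
with any half-pixel ambiguity floored.  The same convention is used by
the 2D and 3D stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.feature import match_template
from skimage.transform import rotate as _sk_rotate

REFERENCE_PIXEL_NM = 16.0


@dataclass
class MatchResult:
    delta_xy: np.ndarray      # (2,) nm, displacement from centered alignment
    peak_value: float
    best_angle_deg: float = 0.0
    valid: bool = True

    def __post_init__(self):
        self.delta_xy = np.asarray(self.delta_xy, float).reshape(2)


def preprocess(
    image: np.ndarray,
    pixel_size_nm: float = 16.0,
    clahe_clip_limit: float = 30.0,
    clahe_tile_size: int = 32,
    log_sigma: float = 4.0,
    variance_floor: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Run the nxcorr preprocessing chain.

    Returns ``(whitened, ok)``; ``ok`` is False for (near-)constant
    images whose grayscale variance is below ``variance_floor`` — those
    cannot be normalized and their matches are treated as outliers.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    img = image.astype(np.float64)
    if img.var() < variance_floor:
        return np.zeros_like(img), False
    scale = REFERENCE_PIXEL_NM / float(pixel_size_nm)
    tile = max(2, int(round(clahe_tile_size * scale)))
    sigma = log_sigma * scale
    # CLAHE works on [0, 1]; skimage's clip limit is normalized to the
    # number of gray levels
    u = img / 255.0
    kernel = (min(tile, img.shape[0]), min(tile, img.shape[1]))
    eq = exposure.equalize_adapthist(
        np.clip(u, 0, 1), kernel_size=kernel,
        clip_limit=min(1.0, clahe_clip_limit / 256.0),
    )
    white = ndimage.gaussian_laplace(eq.astype(np.float64), sigma=sigma)
    white -= white.mean()
    denom = white.std() * np.sqrt(white.size)
    if denom == 0:
        return np.zeros_like(white), False
    return white / denom, True


def _surface_peak(surface: np.ndarray) -> tuple[int, int]:
    """Row-major-first argmax (deterministic tie break)."""
    idx = int(np.argmax(surface))
    return np.unravel_index(idx, surface.shape)


def nxcorr_surface(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Valid-mode ZNCC correlation surface of template against image."""
    image = np.asarray(image, np.float64)
    template = np.asarray(template, np.float64)
    if template.shape[0] >= image.shape[0] or template.shape[1] >= image.shape[1]:
        raise ValueError("template must be strictly smaller than image")
    return match_template(image, template, pad_input=False)


def nxcorr_match(
    image: np.ndarray,
    template: np.ndarray,
    pixel_size_nm: float = 16.0,
    mode: str = "valid",
) -> MatchResult:
    """Best integer-pixel match of ``template`` inside ``image``.

    ``delta_xy`` is the (x, y) displacement, in nm, of the best template
    position relative to the centered nominal alignment (see the module
    docstring for the center convention).

    ``mode="valid"`` requires full template containment; ``mode="full"``
    pads the (whitened, zero-mean) image so partially overlapping
    placements are searched too — used for tile-overlap matching where
    the source quarter crop extends beyond the neighboring tile.
    """
    image = np.asarray(image, np.float64)
    template = np.asarray(template, np.float64)
    if template.std() == 0:
        return MatchResult(np.zeros(2), 0.0, valid=False)
    if mode == "valid":
        surface = nxcorr_surface(image, template)
        r, c = _surface_peak(surface)
        center_r = (image.shape[0] - template.shape[0]) // 2
        center_c = (image.shape[1] - template.shape[1]) // 2
    elif mode == "full":
        if template.shape[0] > image.shape[0] or template.shape[1] > image.shape[1]:
            raise ValueError("template larger than image")
        # zero-pad the (whitened, zero-mean) image so template placements
        # overlapping only partially -- even with the template center off
        # the image -- are searched, as in full FFT correlation
        pr, pc = template.shape[0] // 2 + 1, template.shape[1] // 2 + 1
        padded = np.pad(image, ((pr, pr), (pc, pc)))
        surface = match_template(padded, template, pad_input=True)
        r, c = _surface_peak(surface)
        # surface[r, c] places the template center at padded index (r, c)
        center_r = image.shape[0] // 2 - template.shape[0] // 2
        center_c = image.shape[1] // 2 - template.shape[1] // 2
        r -= pr + template.shape[0] // 2
        c -= pc + template.shape[1] // 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    delta = np.array([c - center_c, r - center_r], float) * pixel_size_nm
    return MatchResult(delta, float(surface[r, c]), valid=True)


def _rotate_crop(template: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the center, cropping to the largest centered square
    region guaranteed free of introduced border values."""
    if angle_deg == 0:
        return template
    rot = _sk_rotate(template.astype(np.float64), angle_deg,
                     resize=False, order=1, mode="constant", cval=0.0)
    h, w = template.shape
    t = np.deg2rad(abs(angle_deg) % 90)
    # inscribed axis-aligned rectangle of the rotated footprint
    shrink = np.cos(t) + np.sin(t)
    ch = int(np.floor(h / shrink))
    cw = int(np.floor(w / shrink))
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    return rot[r0:r0 + ch, c0:c0 + cw]


def nxcorr_match_rotated(
    image: np.ndarray,
    template: np.ndarray,
    angles_deg,
    pixel_size_nm: float = 16.0,
) -> MatchResult:
    """Sweep template rotations; return the highest-peak match.

    The rotated template is cropped to its valid interior, so the
    center convention is preserved per angle.  ``best_angle_deg`` is the
    sweep angle that produced the returned match: a template that was
    *pre-rotated* by +a before matching is recovered at sweep angle -a.
    """
    angles = list(angles_deg)
    if not angles:
        raise ValueError("angle list must be non-empty")
    best = None
    for a in angles:
        tpl = _rotate_crop(np.asarray(template, np.float64), a)
        if tpl.std() == 0:
            continue
        m = nxcorr_match(image, tpl, pixel_size_nm)
        m.best_angle_deg = float(a)
        if m.valid and (best is None or m.peak_value > best.peak_value):
            best = m
    if best is None:
        return MatchResult(np.zeros(2), 0.0, valid=False)
    return best


def sweep_angles(max_deg: float, step_deg: float) -> list[float]:
    """Symmetric rotation sweep, e.g. max 15 step 3 -> [-15, -12, ..., 15]."""
    n = int(round(max_deg / step_deg))
    return [k * step_deg for k in range(-n, n + 1)]
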