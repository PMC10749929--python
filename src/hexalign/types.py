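"""Shared domain types.

Coordinate convention (used everywhere): pixel centers, 0-based, x
rightward / y downward, physical units nm.  Stage transforms map section
pixel space into the shared rough-bounding-box frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Tile:
    """One beam image with its mFOV/beam identity and nominal coordinates.

    ``nominal_xy`` is the acquisition coordinate of the tile center in nm:
    beam coordinates within an mFOV, stage coordinates between mFOVs.
    """

    image: np.ndarray
    mfov_id: int
    beam_id: int
    nominal_xy: np.ndarray
    pixel_size_nm: float

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.nominal_xy = np.asarray(self.nominal_xy, float).reshape(2)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not np.isfinite(self.nominal_xy).all():
            raise ValueError("non-finite nominal coordinates")

    @property
    def shape(self):
        return self.image.shape

    @property
    def size_nm(self) -> np.ndarray:
        h, w = self.image.shape
        return np.array([w, h], float) * self.pixel_size_nm


@dataclass
class RoiSpec:
    """Acquisition region of interest: center (nm, section pixel space
    converted), rotation angle in degrees, and half-size (nm)."""

    center_xy: np.ndarray
    angle_deg: float
    half_size_nm: np.ndarray | None = None

    def __post_init__(self):
        self.center_xy = np.asarray(self.center_xy, float).reshape(2)
        if self.half_size_nm is not None:
            self.half_size_nm = np.asarray(self.half_size_nm, float).reshape(2)


@dataclass
class SectionImage:
    image: np.ndarray
    pixel_size_nm: float
    roi: RoiSpec | None = None
    tissue_mask: np.ndarray | None = None
    mask_pixel_nm: float | None = None
    order_index: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def size_nm(self) -> np.ndarray:
        h, w = self.image.shape
        return np.array([w, h], float) * self.pixel_size_nm
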