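"""Hexagonal measurement grids and neighbor-comparison vector fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def hex_grid(bbox, spacing_nm: float) -> np.ndarray:
    """Hexagonal point lattice covering ``bbox = (x0, y0, x1, y1)`` nm.

    Interior points have six equidistant neighbors at ``spacing_nm``;
    rows are spaced ``spacing * sqrt(3)/2`` apart with alternate rows
    offset by half a spacing.  The lattice extends to the bbox edges so
    the grid fully covers the area.
    """
    x0, y0, x1, y1 = map(float, bbox)
    if spacing_nm <= 0:
        raise ValueError("spacing must be > 0")
    dy = spacing_nm * np.sqrt(3) / 2.0
    rows = int(np.floor((y1 - y0) / dy)) + 1
    pts = []
    for r in range(rows):
        off = (r % 2) * spacing_nm / 2.0
        xs = np.arange(x0 + off, x1 + 1e-9, spacing_nm)
        ys = np.full_like(xs, y0 + r * dy)
        pts.append(np.column_stack([xs, ys]))
    return np.concatenate(pts)


@dataclass
class Comparison:
    """Deltas measured between section ``i`` and its neighbor ``i + n``.

    ``deltas[k]`` is the x,y displacement (nm) that moves content of
    section ``i`` at grid point ``k`` onto section ``i + n``; ``valid``
    marks points where a measurement exists and survived outlier
    rejection; ``replaced`` marks deltas filled in by interpolation.
    """

    i: int
    n: int
    deltas: np.ndarray
    valid: np.ndarray
    replaced: np.ndarray = None
    peak: np.ndarray = None

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, float).reshape(-1, 2)
        self.valid = np.asarray(self.valid, bool).reshape(len(self.deltas))
        if self.replaced is None:
            self.replaced = np.zeros(len(self.deltas), bool)
        self.replaced = np.asarray(self.replaced, bool)


@dataclass
class VectorFieldSet:
    """All neighbor comparisons of a stack on one shared grid."""

    grid: np.ndarray                      # (G, 2) nm
    comparisons: list[Comparison] = field(default_factory=list)
    spacing_nm: float = 0.0
    active: np.ndarray | None = None      # (G,) mask of measured points

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float).reshape(-1, 2)
        if self.active is None:
            self.active = np.ones(len(self.grid), bool)

    @property
    def n_points(self) -> int:
        return len(self.grid)

    def for_pair(self, i: int, n: int) -> Comparison | None:
        for c in self.comparisons:
            if c.i == i and c.n == n:
                return c
        return None
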