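"""Dataset manifests: loading tile collections and ROI annotations.

A dataset is a directory of grayscale image files plus plain-text
tabular manifests:

``tiles.csv``
    columns ``section,mfov,beam,x_nm,y_nm,pixel_size_nm,path`` — one row
    per tile, coordinates are nominal acquisition tile-center positions
    in nm, ``path`` relative to the manifest.
``rois.csv`` (optional)
    columns ``section,cx_nm,cy_nm,angle_deg`` — the acquisition ROI per
    section.
``tears.csv`` (optional)
    columns ``section,ax_nm,ay_nm,bx_nm,by_nm`` — tear stitch pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .types import RoiSpec, Tile

TILE_COLUMNS = ["section", "mfov", "beam", "x_nm", "y_nm", "pixel_size_nm", "path"]


@dataclass
class Dataset:
    """Tiles grouped by section (and within a section ordered by mFOV)."""

    sections: dict[int, list[Tile]] = field(default_factory=dict)
    rois: dict[int, RoiSpec] = field(default_factory=dict)
    tears: dict[int, np.ndarray] = field(default_factory=dict)  # (K, 4) pair coords
    root: Path | None = None

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def n_tiles(self) -> int:
        return sum(len(v) for v in self.sections.values())

    def section_ids(self) -> list[int]:
        return sorted(self.sections)


def _read_rows(path: Path, required: list[str]):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise ValueError(
                f"{path.name}: expected columns {required}, got {reader.fieldnames}"
            )
        yield from reader


def load_manifest(path) -> Dataset:
    """Load a dataset from a ``tiles.csv`` manifest (or its directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / "tiles.csv"
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    root = path.parent
    ds = Dataset(root=root)
    for row in _read_rows(path, TILE_COLUMNS):
        try:
            x, y = float(row["x_nm"]), float(row["y_nm"])
            px = float(row["pixel_size_nm"])
        except ValueError as exc:
            raise ValueError(f"bad numeric value in manifest row {row}: {exc}") from exc
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(px)):
            raise ValueError(f"non-finite coordinate in manifest row: {row}")
        img_path = root / row["path"]
        if not img_path.exists():
            raise FileNotFoundError(
                f"tile image missing for section {row['section']} mfov "
                f"{row['mfov']} beam {row['beam']}: {img_path}"
            )
        tile = Tile(
            image=np.asarray(iio.imread(img_path)),
            mfov_id=int(row["mfov"]),
            beam_id=int(row["beam"]),
            nominal_xy=(x, y),
            pixel_size_nm=px,
        )
        ds.sections.setdefault(int(row["section"]), []).append(tile)
    for tiles in ds.sections.values():
        tiles.sort(key=lambda t: (t.mfov_id, t.beam_id))

    roi_path = root / "rois.csv"
    if roi_path.exists():
        for row in _read_rows(roi_path, ["section", "cx_nm", "cy_nm", "angle_deg"]):
            ds.rois[int(row["section"])] = RoiSpec(
                (float(row["cx_nm"]), float(row["cy_nm"])), float(row["angle_deg"])
            )
    tear_path = root / "tears.csv"
    if tear_path.exists():
        pairs: dict[int, list] = {}
        for row in _read_rows(tear_path, ["section", "ax_nm", "ay_nm", "bx_nm", "by_nm"]):
            pairs.setdefault(int(row["section"]), []).append(
                [float(row[c]) for c in ("ax_nm", "ay_nm", "bx_nm", "by_nm")]
            )
        ds.tears = {k: np.array(v) for k, v in pairs.items()}
    return ds


def save_manifest(ds: Dataset, root) -> Path:
    """Write a dataset to disk in the manifest layout (PNG tiles)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for sec in ds.section_ids():
        for tile in ds.sections[sec]:
            name = f"s{sec:04d}_m{tile.mfov_id:03d}_b{tile.beam_id:03d}.png"
            iio.imwrite(root / name, tile.image.astype(np.uint8))
            rows.append([sec, tile.mfov_id, tile.beam_id,
                         repr(float(tile.nominal_xy[0])), repr(float(tile.nominal_xy[1])),
                         repr(float(tile.pixel_size_nm)), name])
    with open(root / "tiles.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TILE_COLUMNS)
        w.writerows(rows)
    if ds.rois:
        with open(root / "rois.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["section", "cx_nm", "cy_nm", "angle_deg"])
            for sec, roi in sorted(ds.rois.items()):
                w.writerow([sec, repr(float(roi.center_xy[0])),
                            repr(float(roi.center_xy[1])), repr(float(roi.angle_deg))])
    if ds.tears:
        with open(root / "tears.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["section", "ax_nm", "ay_nm", "bx_nm", "by_nm"])
            for sec, arr in sorted(ds.tears.items()):
                for a in arr:
                    w.writerow([sec] + [repr(float(v)) for v in a])
    return root / "tiles.csv"
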