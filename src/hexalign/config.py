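"""Pipeline configuration.

All lengths are stored in nanometers internally.  Image-processing
parameters (CLAHE tile size, LoG sigma, box filters) are quoted for a
16 nm working pixel size and are scaled proportionally when images at a
different pixel size are processed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

UM = 1000.0  # nm per micrometer


@dataclass
class PipelineConfig:
    """Every tunable numeric parameter of the pipeline with its default.

    Defaults correspond to production values for a multi-terabyte
    retina-scale dataset; desk-scale fixtures override the
    geometry-dependent ones.
    """

    # working resolution
    working_pixel_nm: float = 16.0

    # --- 2D tile montaging ------------------------------------------------
    # two-pass outlier box tolerances (half-width boxes around expectation)
    intra_tol_pass1_nm: tuple[float, float] = (768.0, 768.0)
    inter_tol_pass1_nm: tuple[float, float] = (15_440.0, 13_440.0)
    intra_tol_pass2_nm: tuple[float, float] = (64.0, 64.0)
    inter_tol_pass2_nm: tuple[float, float] = (4_480.0, 4_480.0)
    variance_floor: float = 1.0
    replaced_edge_weight: float = 0.5

    # nxcorr preprocessing (at 16 nm)
    clahe_clip_limit: float = 30.0       # OpenCV-convention clip limit
    clahe_tile_size: int = 32
    log_sigma: float = 4.0               # Laplacian-of-Gaussian sigma, px @16nm

    # --- 2D gradient / brightness correction ------------------------------
    gradient_box_nm: float = 1.0 * UM
    large_component_fraction: float = 0.20
    subtile_grid: tuple[int, int] = (3, 3)
    histogram_top_n: int = 32
    subtile_group_size: int = 5_000
    histogram_bins: int = 256
    surface_order: int = 2
    reject_quantiles: tuple[float, float] = (0.25, 0.75)  # Tukey fence base
    intra_feather_nm: float = 0.5 * UM
    inter_feather_nm: float = 3.0 * UM

    # --- 3D rough alignment -----------------------------------------------
    lowe_ratio: float = 1.42
    rough_ransac_tol_nm: float = 5.12 * UM
    min_feature_matches: int = 32
    max_translation_nm: float = 196.0 * UM
    rough_grid_spacing_nm: float = 25.0 * UM
    keypoint_cutoff_nm: float = 60.0 * UM
    rough_block_context: int = 721
    rough_block_solve: int = 241
    feature_pixel_nm: float = 128.0
    rough_n_neighbors: int = 4

    # --- 3D fine alignment -------------------------------------------------
    fine_grid_spacing_nm: float = 16.0 * UM
    fine_src_crop_nm: float = 32.0 * UM
    fine_dst_crop_nm: float = 4.8 * UM
    fine_n_neighbors: int = 4
    rotation_sweep_deg: float = 15.0
    rotation_step_deg: float = 3.0
    fine_ransac_tol_nm: float = 12.0 * UM
    reconsider_diameter_nm: float = 57.0 * UM
    replaced_delta_weight: float = 0.5
    affine_filter_box_nm: float = 61.0 * UM
    neighbor_weights: tuple[float, ...] = (1.0, 1.0, 0.4, 0.1)
    fine_l2: float = 0.0
    ultra_grid_spacing_nm: float = 2.0 * UM
    ultra_src_crop_nm: float = 12.8 * UM
    ultra_dst_crop_nm: float = 3.2 * UM
    ultra_n_neighbors: int = 2
    ultra_l2: float = 0.05
    roi_scale: float = 1.10

    # --- tissue masks / contrast -------------------------------------------
    mask_pixel_nm: float = 1024.0

    # --- export -------------------------------------------------------------
    export_block_overlap_px: int = 8
    export2d_overlap_nm: float = 8.0 * UM

    # --- MLS ----------------------------------------------------------------
    mls_alpha: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "variance_floor", "gradient_box_nm", "rough_ransac_tol_nm",
            "fine_ransac_tol_nm", "rough_grid_spacing_nm",
            "fine_grid_spacing_nm", "ultra_grid_spacing_nm",
            "working_pixel_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a flat YAML mapping of overrides on top of the defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key, val in list(data.items()):
            if isinstance(val, list):
                data[key] = tuple(val)
        return cls(**data)
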