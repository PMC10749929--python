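import numpy as np
import pytest

from hexalign.config import PipelineConfig
from hexalign.synthetic import (
    StackFixtureSpec,
    TileFixtureSpec,
    generate_stack_fixture,
    generate_tile_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tile_fixture():
    """One 7-beam mFOV pair, modest jitter, no brightness artifacts."""
    return generate_tile_fixture(TileFixtureSpec(
        seed=0, n_beams=7, n_mfovs=2, jitter_px=0.5,
        intra_overlap_nm=16.0 * 24, inter_overlap_nm=16.0 * 36))


@pytest.fixture(scope="session")
def artifact_tile_fixture():
    """Hex tiles with planted jitter, gradients and brightness offsets."""
    return generate_tile_fixture(TileFixtureSpec(
        seed=2, n_beams=7, n_mfovs=9, jitter_px=0.5,
        tile_shape_px=(160, 160),
        intra_overlap_nm=16.0 * 28, inter_overlap_nm=16.0 * 40,
        gradient_range=(0.8, 1.2), offset_range_gray=10.0))


@pytest.fixture(scope="session")
def elastic_stack():
    """Stack warped by smooth per-section elastic fields only."""
    return generate_stack_fixture(StackFixtureSpec(
        seed=3, n_sections=8, section_shape_px=(320, 320),
        transform_family="elastic", max_rotation_deg=0.0,
        max_translation_px=0.0, elastic_magnitude_px=8.0,
        elastic_smoothness_px=80.0))


@pytest.fixture(scope="session")
def rigid_stack():
    """Stack with smooth per-section rigid perturbations."""
    return generate_stack_fixture(StackFixtureSpec(
        seed=1, n_sections=10, section_shape_px=(288, 288),
        transform_family="rigid", max_rotation_deg=8.0,
        max_translation_px=12.0))


def montage_vs_phantom(section, fix):
    """Correlation / MAE between a rendered montage and the phantom it
    was cut from (global brightness gauge removed from the MAE)."""
    px = fix.tiles[0].pixel_size_nm
    r0 = int(round((section.origin_nm[1] - fix.phantom_origin_nm[1]) / px))
    c0 = int(round((section.origin_nm[0] - fix.phantom_origin_nm[0]) / px))
    H, W = section.image.shape
    ph = fix.phantom[r0:r0 + H, c0:c0 + W].astype(float)
    m = section.coverage & (ph > 0)
    d = section.image.astype(float) - ph
    gauge = np.median(d[m])
    corr = np.corrcoef(section.image.astype(float)[m], ph[m])[0, 1]
    return corr, np.abs(d[m] - gauge).mean()
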