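"""Coarse ROI alignment and feature-based rough alignment."""

import numpy as np
import pytest

from hexalign.config import PipelineConfig
from hexalign.grids import Comparison, VectorFieldSet, hex_grid
from hexalign.lss import DeltaGraph, solve
from hexalign.rough3d import (
    PairResult,
    affines_to_fields,
    coarse_align,
    detect_features,
    match_sections,
    neighbor_affines,
    refit_section_affine,
    rough_delta_solve,
)
from hexalign.synthetic import StackFixtureSpec, generate_stack_fixture, phantom_texture
from hexalign.transforms2d import AffineTransform2D, decompose
from hexalign.types import RoiSpec, SectionImage

PX = 16.0


class TestCoarseAlign:
    def test_zero_angle_center_is_crop(self):
        img = phantom_texture((256, 256), seed=0)
        sec = SectionImage(img, PX)
        roi = RoiSpec((128 * PX, 128 * PX), 0.0)
        bbox = (64 * PX, 64 * PX, 192 * PX, 192 * PX)
        out = coarse_align(sec, roi, bbox)
        assert np.abs(out.image.astype(int) - img[64:192, 64:192].astype(int)).max() <= 1

    def test_known_rotation_undone(self):
        """A section rotated by 23 degrees with a matching ROI angle is
        registered to the unrotated reference after coarse alignment."""
        from skimage.transform import rotate
        ref = phantom_texture((384, 384), seed=1)
        rot = (rotate(ref.astype(float) / 255, 23.0, resize=False,
                      center=(192, 192), order=1) * 255).astype(np.uint8)
        # skimage rotate by +a maps content such that the ROI records -a
        sec = SectionImage(rot, PX)
        roi = RoiSpec((192 * PX, 192 * PX), -23.0)
        bbox = (96 * PX, 96 * PX, 288 * PX, 288 * PX)
        out = coarse_align(sec, roi, bbox)
        ref_crop = ref[96:288, 96:288].astype(float)
        inner = np.s_[40:-40, 40:-40]
        a, b = out.image.astype(float)[inner], ref_crop[inner]
        cc = ((a - a.mean()) * (b - b.mean())).mean() / (a.std() * b.std())
        assert cc > 0.95

    def test_roi_outside_image_errors(self):
        sec = SectionImage(np.zeros((64, 64), np.uint8), PX)
        with pytest.raises(ValueError):
            coarse_align(sec, RoiSpec((200 * PX, 200 * PX), 0.0),
                         (0, 0, 64 * PX, 64 * PX))


class TestLoweMatching:
    def test_ratio_threshold(self):
        """Nearest distance 1.0 with second-nearest 1.5 passes the 1.42
        ratio; second-nearest 1.3 does not."""
        kpA = np.array([[0.0, 0.0], [10.0, 10.0]])
        base = np.zeros(8)
        # query 0: nearest at d=1, second at d=1.5 -> kept
        # query 1: nearest at d=1, second at d=1.3 -> rejected
        descA = np.stack([base, base + 10])
        descB = np.stack([base + np.array([1, 0, 0, 0, 0, 0, 0, 0]),
                          base + np.array([0, 1.5, 0, 0, 0, 0, 0, 0]),
                          base + 10 + np.array([1, 0, 0, 0, 0, 0, 0, 0]),
                          base + 10 + np.array([0, 1.3, 0, 0, 0, 0, 0, 0])])
        kpB = np.array([[1.0, 0.0], [2.0, 0.0], [11.0, 10.0], [12.0, 10.0]])
        corr = match_sections((kpA, descA), (kpB, descB), lowe_ratio=1.42)
        assert len(corr) == 1
        assert tuple(corr.src[0]) == (0.0, 0.0)

    def test_identical_images_self_match(self):
        img = phantom_texture((256, 256), seed=2)
        feat = detect_features(img)
        corr = match_sections(feat, feat)
        assert len(corr) > 0.9 * len(feat[0])
        assert np.abs(corr.src - corr.dst).max() < 1e-9

    def test_random_descriptors_rarely_match(self, rng):
        kpA = rng.uniform(0, 100, (200, 2))
        kpB = rng.uniform(0, 100, (200, 2))
        dA = rng.standard_normal((200, 128))
        dB = rng.standard_normal((200, 128))
        corr = match_sections((kpA, dA), (kpB, dB))
        assert len(corr) < 40  # ratio test rejects the bulk


@pytest.fixture(scope="module")
def rigid_feats(rigid_stack_mod):
    return [detect_features(s.image) for s in rigid_stack_mod.sections]


@pytest.fixture(scope="module")
def rigid_stack_mod():
    return generate_stack_fixture(StackFixtureSpec(
        seed=1, n_sections=10, section_shape_px=(288, 288),
        transform_family="rigid", max_rotation_deg=8.0,
        max_translation_px=12.0))


class TestNeighborAffines:
    def test_recovers_planted_pairwise_transform(self, rigid_stack_mod, rigid_feats):
        cfg = PipelineConfig(min_feature_matches=20)
        pairs = neighbor_affines(rigid_feats, PX, cfg, seed=0, n_neighbors=1)
        probes = np.random.default_rng(0).uniform(60, 230, (15, 2))
        T = rigid_stack_mod.transforms
        for pr in pairs:
            assert pr.transform is not None
            i, j = pr.i, pr.i + pr.n
            truth = T[j].inverse().apply(T[i].apply(probes))
            est = pr.transform.apply(probes * PX) / PX
            assert np.linalg.norm(truth - est, axis=1).max() < 1.0
            ang_true = decompose(T[j].inverse().compose_with(T[i])).angle_deg
            ang_est = decompose(pr.transform).angle_deg
            assert abs(ang_true - ang_est) < 0.1

    def test_too_few_matches_flagged(self, rigid_stack_mod, rigid_feats):
        cfg = PipelineConfig(min_feature_matches=10 ** 6)
        pairs = neighbor_affines(rigid_feats[:3], PX, cfg, seed=0, n_neighbors=1)
        assert all(p.transform is None for p in pairs)
        assert all(p.flag for p in pairs)

    def test_excess_translation_flagged(self, rigid_stack_mod, rigid_feats):
        cfg = PipelineConfig(min_feature_matches=20,
                             max_translation_nm=1.0)  # 1 nm: everything trips
        pairs = neighbor_affines(rigid_feats[:3], PX, cfg, seed=0, n_neighbors=1)
        assert all(p.transform is None for p in pairs)


class TestAffinesToFields:
    def _pairs(self, T):
        return [PairResult(0, 1, T, 100,
                           inlier_keypoints=np.array([[0.0, 0.0], [4000.0, 4000.0]]))]

    def test_identity_gives_zero_field(self):
        cfg = PipelineConfig(rough_grid_spacing_nm=1000.0,
                             keypoint_cutoff_nm=1e9)
        f = affines_to_fields(self._pairs(AffineTransform2D.identity()),
                              (0, 0, 4000, 4000), cfg)
        assert np.allclose(f.comparisons[0].deltas, 0)

    def test_translation_gives_constant_field(self):
        cfg = PipelineConfig(rough_grid_spacing_nm=1000.0,
                             keypoint_cutoff_nm=1e9)
        T = AffineTransform2D(np.eye(2), np.array([7.0, -3.0]))
        f = affines_to_fields(self._pairs(T), (0, 0, 4000, 4000), cfg)
        assert np.allclose(f.comparisons[0].deltas, [7.0, -3.0])

    def test_rotation_field_grows_with_radius(self):
        cfg = PipelineConfig(rough_grid_spacing_nm=500.0,
                             keypoint_cutoff_nm=1e9)
        center = np.array([2000.0, 2000.0])
        T = AffineTransform2D.rotation(5.0, center=center)
        f = affines_to_fields(self._pairs(T), (0, 0, 4000, 4000), cfg)
        r = np.linalg.norm(f.grid - center, axis=1)
        mag = np.linalg.norm(f.comparisons[0].deltas, axis=1)
        expected = 2 * np.sin(np.deg2rad(5.0) / 2) * r
        assert np.allclose(mag, expected, atol=1e-6)

    def test_keypoint_cutoff_invalidates_far_points(self):
        cfg = PipelineConfig(rough_grid_spacing_nm=500.0,
                             keypoint_cutoff_nm=1500.0)
        f = affines_to_fields(self._pairs(AffineTransform2D.identity()),
                              (0, 0, 4000, 4000), cfg)
        c = f.comparisons[0]
        kp = np.array([[0.0, 0.0], [4000.0, 4000.0]])
        for g, v in zip(f.grid, c.valid):
            d = np.linalg.norm(kp - g, axis=1).min()
            assert v == (d <= 1500.0)


class TestRoughDeltaSolve:
    def _fields(self, grid, n_sections, per_section_u, nmax=2):
        """Build comparison deltas from known per-section content
        displacements u_i: delta(i, i+n) = u_{i+n} - u_i."""
        fs = VectorFieldSet(grid)
        for i in range(n_sections):
            for n in range(1, nmax + 1):
                if i + n >= n_sections:
                    continue
                d = per_section_u[i + n] - per_section_u[i]
                fs.comparisons.append(Comparison(
                    i, n, np.tile(d, (len(grid), 1)),
                    np.ones(len(grid), bool)))
        return fs

    def test_all_zero_fields_zero_solution(self):
        grid = hex_grid((0, 0, 2000, 2000), 500.0)
        u = np.zeros((10, 2))
        res = rough_delta_solve(self._fields(grid, 10, u), 10,
                                block_context=10, block_solve=10)
        assert all(np.allclose(r, 0) for r in res)

    def test_single_perturbed_section_recovered(self):
        """One section's content displaced by +d: its resolved lookup is
        about +d (rendered content moves by -d, up to the removed linear
        trend), others near zero."""
        grid = hex_grid((0, 0, 2000, 2000), 500.0)
        n = 20
        u = np.zeros((n, 2))
        u[10] = (160.0, 0.0)  # 10 px at 16 nm
        res = rough_delta_solve(self._fields(grid, n, u, nmax=2), n,
                                block_context=n, block_solve=n)
        corr10 = res[10].mean(0)
        assert abs(corr10[0] - 160.0) < 0.15 * 160
        others = np.array([res[i].mean(0) for i in range(n) if i != 10])
        assert np.abs(others[:, 0]).max() < 0.2 * 160

    def test_matches_dense_per_point_oracle(self, rng):
        grid = hex_grid((0, 0, 1000, 1000), 500.0)
        n = 12
        u = rng.uniform(-50, 50, (n, 2))
        fields = self._fields(grid, n, u, nmax=3)
        res = rough_delta_solve(fields, n, block_context=n, block_solve=n,
                                detrend=False)
        edges = [(c.i, c.i + c.n) for c in fields.comparisons]
        deltas = np.array([u[j] - u[i] for i, j in edges])
        oracle = solve(DeltaGraph(n, edges, deltas)).coords
        for g in range(len(grid)):
            got = np.array([res[i][g] for i in range(n)])
            assert np.abs(got - oracle).max() < 1e-8


class TestRefit:
    def test_noshear_field_exact_recovery(self):
        grid = hex_grid((0, 0, 4000, 4000), 500.0)
        A = AffineTransform2D.rotation(4.0).linear @ np.diag([1.02, 0.98])
        T = AffineTransform2D(A, np.array([30.0, -20.0]))
        fit = refit_section_affine(grid, T.apply(grid) - grid)
        assert np.allclose(fit.linear, T.linear, atol=1e-9)
        assert np.allclose(fit.translation, T.translation, atol=1e-6)

    def test_sheared_field_refits_with_zero_shear(self):
        """The constrained refit cannot carry shear (the full-affine
        pathology), and leaves a nonzero residual on a sheared field."""
        grid = hex_grid((0, 0, 4000, 4000), 500.0)
        Sh = AffineTransform2D(np.array([[1.0, 0.15], [0.0, 1.0]]), np.zeros(2))
        deltas = Sh.apply(grid) - grid
        fit_ns = refit_section_affine(grid, deltas, constraint="noshear")
        fit_full = refit_section_affine(grid, deltas, constraint="full")
        assert decompose(fit_ns).shear_x == 0.0
        assert abs(decompose(fit_full).shear_x - 0.15) < 1e-9
        assert not np.allclose(fit_ns.linear, Sh.linear, atol=1e-3)

    def test_too_few_points_identity(self):
        grid = np.array([[0.0, 0.0], [100.0, 0.0]])
        fit = refit_section_affine(grid, np.zeros((2, 2)),
                                   valid=np.array([True, False]))
        assert fit == AffineTransform2D.identity()
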