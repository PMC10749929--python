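"""Elastic fine alignment: grids, delta measurement, outlier handling,
affine filtering and the per-grid-point solve."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from hexalign.fine3d import (
    FineParams,
    affine_filter,
    detect_outliers,
    fine_delta_solve,
    make_masked_grid,
    measure_fine_deltas,
    replace_outliers,
)
from hexalign.grids import Comparison, VectorFieldSet, hex_grid
from hexalign.lss import DeltaGraph, solve
from hexalign.synthetic import phantom_texture, smooth_field
from hexalign.transforms2d import AffineTransform2D
from hexalign.types import RoiSpec

PX = 16.0


def small_params(**kw):
    defaults = dict(grid_spacing_nm=24 * PX, src_crop_nm=64 * PX,
                    dst_crop_nm=24 * PX, n_neighbors=2,
                    rotation_sweep_deg=6.0, rotation_step_deg=6.0,
                    ransac_tol_nm=8 * PX, reconsider_diameter_nm=80 * PX,
                    affine_filter_box_nm=90 * PX, neighbor_weights=(1.0, 1.0))
    defaults.update(kw)
    return FineParams(**defaults)


class TestMaskedGrid:
    def test_no_constraints_all_active(self):
        grid, active = make_masked_grid((0, 0, 2000, 2000), 400.0)
        assert active.all()
        assert len(grid) > 20

    def test_roi_half_restricts(self):
        roi = RoiSpec((1000.0, 1000.0), 0.0, half_size_nm=(450.0, 2000.0))
        grid, active = make_masked_grid((0, 0, 2000, 2000), 200.0, roi,
                                        roi_scale=1.0)
        inside = np.abs(grid[:, 0] - 1000.0) <= 450.0
        assert np.array_equal(active, inside)

    def test_hex_geometry_six_equidistant_neighbors(self):
        grid, _ = make_masked_grid((0, 0, 4000, 4000), 400.0)
        tree = cKDTree(grid)
        center = grid[np.argmin(np.linalg.norm(grid - [2000, 2000], axis=1))]
        d, _ = tree.query(center, k=7)
        assert np.allclose(d[1:], 400.0, rtol=1e-6)

    def test_mask_restricts(self):
        mask = np.zeros((4, 4), bool)
        mask[:, :2] = True  # left half at 1024 nm/px
        grid, active = make_masked_grid((0, 0, 4000, 4000), 400.0,
                                        mask=mask, mask_pixel_nm=1024.0,
                                        mask_dilate_px=1)
        assert active[grid[:, 0] < 1000].all()
        assert not active[grid[:, 0] > 3500].any()


class TestMeasureDeltas:
    def test_identical_sections_zero_deltas(self):
        img = phantom_texture((256, 256), seed=0)
        imgs = [img, img, img]
        grid, active = make_masked_grid((40 * PX, 40 * PX, 216 * PX, 216 * PX),
                                        40 * PX)
        fields = measure_fine_deltas(imgs, grid, active, small_params(), PX)
        for c in fields.comparisons:
            assert c.valid[active].mean() > 0.9
            assert np.abs(c.deltas[c.valid]).max() <= PX
            assert c.peak[c.valid].min() > 0.8

    def test_planted_uniform_shift_recovered(self):
        img = phantom_texture((288, 288), seed=1)
        shifted = np.roll(img, (4, -6), axis=(0, 1))  # content moves +4 rows, -6 cols
        grid, active = make_masked_grid((48 * PX, 48 * PX, 240 * PX, 240 * PX),
                                        40 * PX)
        fields = measure_fine_deltas([img, shifted], grid, active,
                                     small_params(n_neighbors=1,
                                                  neighbor_weights=(1.0,)), PX)
        c = fields.comparisons[0]
        good = c.valid & active
        med = np.median(c.deltas[good], axis=0) / PX
        assert tuple(med) == (-6.0, 4.0)

    def test_crop_out_of_bounds_skipped(self):
        img = phantom_texture((128, 128), seed=2)
        grid = np.array([[4 * PX, 4 * PX], [64 * PX, 64 * PX]])
        fields = measure_fine_deltas([img, img], grid, np.ones(2, bool),
                                     small_params(n_neighbors=1,
                                                  neighbor_weights=(1.0,)), PX)
        c = fields.comparisons[0]
        assert not c.valid[0]   # crop would leave the image
        assert c.valid[1]


class TestOutlierDetection:
    def _quad_field(self, grid):
        x, y = grid[:, 0] / 4000.0, grid[:, 1] / 4000.0
        return np.column_stack([50 * x ** 2 - 30 * y + 10,
                                40 * x * y + 20 * y ** 2])

    def test_clean_quadratic_field_all_inliers(self):
        grid = hex_grid((0, 0, 4000, 4000), 300.0)
        deltas = self._quad_field(grid)
        params = small_params(ransac_tol_nm=150.0)
        inlier, frac = detect_outliers(grid, deltas, np.ones(len(grid), bool),
                                       params, seed=0)
        assert frac == 1.0

    def test_planted_outliers_flagged_no_inliers_lost(self, rng):
        grid = hex_grid((0, 0, 4000, 4000), 300.0)
        deltas = self._quad_field(grid)
        n = len(grid)
        out_idx = rng.choice(n, n // 10, replace=False)
        deltas = deltas.copy()
        deltas[out_idx] += rng.uniform(2000, 5000, (len(out_idx), 2)) \
            * rng.choice([-1, 1], (len(out_idx), 2))
        params = small_params(ransac_tol_nm=150.0)
        inlier, frac = detect_outliers(grid, deltas, np.ones(n, bool),
                                       params, seed=0)
        assert not inlier[out_idx].any()
        clean = np.setdiff1d(np.arange(n), out_idx)
        assert inlier[clean].all()

    def test_borderline_delta_readmitted(self):
        """A delta rejected by the quadratic model but consistent with
        its local neighborhood is re-admitted."""
        grid = hex_grid((0, 0, 4000, 4000), 300.0)
        n = len(grid)
        deltas = np.zeros((n, 2))
        # a coherent local patch deviating from the global model
        center = np.array([2000.0, 2000.0])
        patch = np.linalg.norm(grid - center, axis=1) < 500.0
        deltas[patch] = (400.0, 0.0)
        params = small_params(ransac_tol_nm=100.0,
                              reconsider_diameter_nm=1000.0)
        inlier, _ = detect_outliers(grid, deltas, np.ones(n, bool),
                                    params, seed=0)
        assert inlier[patch].mean() > 0.7


class TestReplaceAndFilter:
    def test_mls_replacement_reproduces_global_rigid(self, rng):
        grid = hex_grid((0, 0, 4000, 4000), 400.0)
        T = AffineTransform2D.rotation(3.0, center=(2000, 2000))
        deltas = T.apply(grid) - grid
        inlier = rng.random(len(grid)) > 0.3
        corrupted = deltas.copy()
        corrupted[~inlier] = 1e5  # garbage where outliers sat
        out, replaced = replace_outliers(grid, corrupted, inlier,
                                         np.ones(len(grid), bool))
        assert np.abs(out - deltas).max() < 1e-6
        assert np.array_equal(replaced, ~inlier)

    def test_extrapolation_bounded(self, rng):
        grid = hex_grid((0, 0, 4000, 4000), 400.0)
        inner = (np.abs(grid - 2000) < 1000).all(axis=1)
        deltas = np.zeros((len(grid), 2))
        deltas[inner] = rng.uniform(-100, 100, (inner.sum(), 2))
        out, _ = replace_outliers(grid, deltas, inner,
                                  np.ones(len(grid), bool))
        max_in = np.linalg.norm(deltas[inner], axis=1).max()
        assert np.linalg.norm(out, axis=1).max() <= 2 * max_in

    def test_too_few_inliers_errors(self):
        grid = hex_grid((0, 0, 1000, 1000), 400.0)
        with pytest.raises(ValueError):
            replace_outliers(grid, np.zeros((len(grid), 2)),
                             np.zeros(len(grid), bool),
                             np.ones(len(grid), bool))

    def test_affine_filter_fixes_affine_fields(self):
        grid = hex_grid((0, 0, 4000, 4000), 300.0)
        T = AffineTransform2D(np.array([[1.01, 0.02], [-0.01, 0.99]]),
                              np.array([30.0, -10.0]))
        deltas = T.apply(grid) - grid
        out = affine_filter(grid, deltas, 900.0)
        assert np.abs(out - deltas).max() < 1e-9

    def test_affine_filter_suppresses_spike(self):
        grid = hex_grid((0, 0, 4000, 4000), 300.0)
        deltas = np.zeros((len(grid), 2))
        k = np.argmin(np.linalg.norm(grid - [2000, 2000], axis=1))
        deltas[k] = (800.0, 0.0)
        out = affine_filter(grid, deltas, 900.0)
        assert np.linalg.norm(out[k]) < np.linalg.norm(deltas[k]) / 10

    def test_affine_filter_attenuation_grows_with_frequency(self):
        grid = hex_grid((0, 0, 8000, 8000), 200.0)
        box = 1200.0
        gains = []
        for wavelength in (8000.0, 2400.0, 800.0):
            deltas = np.column_stack([
                100 * np.sin(2 * np.pi * grid[:, 0] / wavelength),
                np.zeros(len(grid))])
            out = affine_filter(grid, deltas, box)
            gains.append(np.linalg.norm(out) / np.linalg.norm(deltas))
        assert gains[0] > 0.9
        assert gains[0] > gains[1] > gains[2]


class TestFineDeltaSolve:
    def _fields(self, grid, n_sections, u, nmax=2, replaced=None):
        fs = VectorFieldSet(grid)
        for i in range(n_sections):
            for n in range(1, nmax + 1):
                if i + n >= n_sections:
                    continue
                d = u[i + n] - u[i]   # (G, 2) per-section content shifts
                fs.comparisons.append(Comparison(
                    i, n, d, np.ones(len(grid), bool),
                    replaced=replaced[(i, n)] if replaced else None))
        return fs

    def test_all_zero(self):
        grid = hex_grid((0, 0, 1000, 1000), 400.0)
        u = np.zeros((6, len(grid), 2))
        solved, mags = fine_delta_solve(
            self._fields(grid, 6, u),
            6, small_params())
        assert np.allclose(mags, 0)

    def test_planted_smooth_field_recovered(self):
        grid = hex_grid((200, 200, 3800, 3800), 300.0)
        n = 10
        u = np.zeros((n, len(grid), 2))
        f = smooth_field((40, 40), seed=5, magnitude_px=5.0,
                         smoothness_px=12.0)
        gi = np.clip((grid / 100.0).astype(int), 0, 39)
        u[4] = f[gi[:, 1], gi[:, 0]] * 100.0
        solved, mags = fine_delta_solve(self._fields(grid, n, u), n,
                                        small_params())
        err4 = solved[4] - u[4]
        err4 -= err4.mean(0)
        assert np.sqrt((err4 ** 2).sum(1).mean()) < 0.15 * np.abs(u[4]).max()

    def test_matches_dense_oracle_with_weights(self, rng):
        grid = hex_grid((0, 0, 800, 800), 400.0)
        n = 15
        u = rng.uniform(-50, 50, (n, len(grid), 2))
        replaced = {}
        for i in range(n):
            for m in (1, 2):
                if i + m < n:
                    replaced[(i, m)] = rng.random(len(grid)) < 0.3
        params = small_params(neighbor_weights=(1.0, 0.4), l2=0.02)
        fields = self._fields(grid, n, u, replaced=replaced)
        solved, _ = fine_delta_solve(fields, n, params)
        for g in range(len(grid)):
            edges, deltas, w = [], [], []
            for c in fields.comparisons:
                edges.append((c.i, c.i + c.n))
                deltas.append(c.deltas[g])
                wt = params.neighbor_weights[c.n - 1]
                if c.replaced[g]:
                    wt *= 0.5
                w.append(wt)
            oracle = solve(DeltaGraph(n, edges, np.array(deltas), np.array(w)),
                           l2=0.02, remove_offset=False).coords
            got = np.array([solved[i][g] for i in range(n)])
            assert np.abs(got - oracle).max() < 1e-8
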