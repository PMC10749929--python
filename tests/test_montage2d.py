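"""Hexagonal tile montaging: neighbor graph, deltas, outliers, solve,
rendering."""

import numpy as np
import pytest

from hexalign.config import PipelineConfig
from hexalign.montage2d import (
    MfovLayout,
    build_neighbor_graph,
    hex_axial_coords,
    hex_ring_count,
    measure_deltas,
    montage_section,
    outlier_two_pass,
    render_montage,
    solve_section,
)
from hexalign.synthetic import TileFixtureSpec, generate_tile_fixture
from hexalign.types import Tile

from conftest import montage_vs_phantom

PX = 16.0


class TestLayout:
    def test_centered_hex_numbers(self):
        assert [hex_ring_count(k) for k in range(6)] == [1, 7, 19, 37, 61, 91]

    @pytest.mark.parametrize("n", [7, 19, 61, 91])
    def test_axial_coords_unique(self, n):
        ax = hex_axial_coords(n)
        assert len(set(map(tuple, ax))) == n

    def test_interior_beam_has_six_neighbors(self):
        """The center beam's six lattice neighbors come in the two
        characteristic pitches of the offset-row layout."""
        layout = MfovLayout((96, 96), PX, n_beams=19)
        pos = layout.beam_positions()
        d = np.linalg.norm(pos - pos[0], axis=1)
        expected = {round(layout.dx, 6),
                    round(np.hypot(layout.dx / 2, layout.dy), 6)}
        six = np.sort(d[d > 0])[:6]
        assert {round(v, 6) for v in six} <= expected
        # and nothing else is as close
        assert np.sort(d[d > 0])[6] > max(six) - 1e-6


class TestNeighborGraph:
    def test_seven_tile_degrees(self):
        fix = generate_tile_fixture(TileFixtureSpec(seed=0, n_beams=7, n_mfovs=1))
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        deg = np.zeros(7, int)
        for e in edges:
            deg[e.src] += 1
            deg[e.dst] += 1
        center = [t.beam_id for t in fix.tiles].index(0)
        assert deg[center] == 6
        assert sorted(np.delete(deg, center)) == [3] * 6
        assert len(edges) == len({(e.src, e.dst) for e in edges})

    def test_single_mfov_has_no_inter_edges(self):
        fix = generate_tile_fixture(TileFixtureSpec(seed=0, n_beams=7, n_mfovs=1))
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        assert all(e.kind == "intra" for e in edges)

    def test_inter_edges_only_between_overlapping_tiles(self, small_tile_fixture):
        fix = small_tile_fixture
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        inter = [e for e in edges if e.kind == "inter"]
        assert inter
        size = fix.layout.tile_size_nm
        for e in inter:
            gap = np.abs(fix.tiles[e.dst].nominal_xy - fix.tiles[e.src].nominal_xy)
            assert (gap < size).all()
            assert fix.tiles[e.src].mfov_id != fix.tiles[e.dst].mfov_id


class TestMeasureDeltas:
    def test_exact_cut_recovers_nominal_deltas(self):
        fix = generate_tile_fixture(TileFixtureSpec(
            seed=0, n_beams=7, n_mfovs=1, jitter_px=0.0,
            intra_overlap_nm=PX * 24, inter_overlap_nm=PX * 36))
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        g = measure_deltas(fix.tiles, edges)
        true = fix.true_positions
        errs = [np.abs(g.deltas[k] - (true[e.dst] - true[e.src])).max() / PX
                for k, e in enumerate(edges)]
        assert np.median(errs) <= 1.0
        assert sum(e <= 1.0 for e in errs) >= 0.8 * len(errs)

    def test_blank_tile_edges_flagged(self):
        fix = generate_tile_fixture(TileFixtureSpec(
            seed=0, n_beams=7, n_mfovs=1, jitter_px=0.0,
            intra_overlap_nm=PX * 24, inter_overlap_nm=PX * 36))
        blank_idx = 3
        fix.tiles[blank_idx].image = np.full_like(fix.tiles[blank_idx].image, 128)
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        g = measure_deltas(fix.tiles, edges)
        for k, e in enumerate(edges):
            if blank_idx in (e.src, e.dst):
                assert g.outlier[k]

    def test_planted_jitter_equivariance(self):
        """Shifting one tile's cut position shifts its edge deltas by
        exactly the planted offset."""
        base = generate_tile_fixture(TileFixtureSpec(
            seed=4, n_beams=7, n_mfovs=1, jitter_px=0.0,
            intra_overlap_nm=PX * 24, inter_overlap_nm=PX * 36))
        edges = build_neighbor_graph(base.tiles, base.layout)
        g0 = measure_deltas(base.tiles, edges)
        # re-cut tile 0 with a (3, -2) px offset
        t0 = base.tiles[0]
        h, w = t0.image.shape
        lo = base.phantom_origin_nm
        c0 = int(round((base.true_positions[0, 0] - lo[0]) / PX - w / 2)) + 3
        r0 = int(round((base.true_positions[0, 1] - lo[1]) / PX - h / 2)) - 2
        t0.image = base.phantom[r0:r0 + h, c0:c0 + w]
        g1 = measure_deltas(base.tiles, edges)
        gross = 0
        for k, e in enumerate(edges):
            d = (g1.deltas[k] - g0.deltas[k]) / PX
            if e.src == 0 or e.dst == 0:
                sign = -1.0 if e.src == 0 else 1.0
                if np.abs(d - (sign * 3.0, sign * -2.0)).max() > 1.0:
                    gross += 1  # ambiguous peak; the outlier pass handles it
            else:
                assert tuple(d) == (0.0, 0.0)
        assert gross <= 1


class TestOutlierTwoPass:
    def _fixture_graph(self):
        fix = generate_tile_fixture(TileFixtureSpec(
            seed=0, n_beams=7, n_mfovs=2, jitter_px=0.0,
            intra_overlap_nm=PX * 24, inter_overlap_nm=PX * 36))
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        g = measure_deltas(fix.tiles, edges)
        # discard measurement noise: use exact deltas
        true = fix.true_positions
        g.deltas = np.array([true[e.dst] - true[e.src] for e in edges])
        g.outlier[:] = False
        return fix, edges, g

    def test_consistent_deltas_zero_flags(self):
        fix, edges, g = self._fixture_graph()
        out = outlier_two_pass(g, edges, fix.tiles)
        assert out.replaced.sum() == 0
        assert np.array_equal(out.deltas, g.deltas)

    def test_gross_outlier_flagged_pass1_and_replaced(self):
        fix, edges, g = self._fixture_graph()
        k = next(i for i, e in enumerate(edges) if e.kind == "intra")
        g.deltas[k] += (5000.0, 0.0)  # 5 um: outside the 768 nm box
        out = outlier_two_pass(g, edges, fix.tiles)
        assert out.replaced[k]
        same_dir = [i for i, e in enumerate(edges)
                    if e.kind == "intra" and e.direction == edges[k].direction
                    and i != k]
        med = np.median(g.deltas[same_dir], axis=0)
        assert np.allclose(out.deltas[k], med)
        assert out.weights[k] == 0.5

    def test_small_deviation_caught_in_pass2_only(self):
        fix, edges, g = self._fixture_graph()
        k = next(i for i, e in enumerate(edges) if e.kind == "intra")
        g.deltas[k] += (100.0, 0.0)  # inside 768 nm pass-1, outside 64 nm pass-2
        out = outlier_two_pass(g, edges, fix.tiles)
        assert out.replaced[k]
        # pass-1 alone would keep it
        cfg = PipelineConfig(intra_tol_pass2_nm=(1e9, 1e9),
                             inter_tol_pass2_nm=(1e9, 1e9))
        out1 = outlier_two_pass(g, edges, fix.tiles, cfg)
        assert not out1.replaced[k]


class TestSolveAndRender:
    def test_ground_truth_recovery(self, small_tile_fixture):
        fix = small_tile_fixture
        section, solved, graph, edges = montage_section(fix.tiles, fix.layout)
        err = solved.coords - fix.true_positions
        err -= err.mean(0)
        assert np.sqrt((err ** 2).sum(1).mean()) / PX < 1.0

    def test_consistent_deltas_zero_residuals(self):
        fix = generate_tile_fixture(TileFixtureSpec(
            seed=0, n_beams=7, n_mfovs=1, jitter_px=0.0))
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        from hexalign.lss import DeltaGraph
        true = fix.true_positions
        g = DeltaGraph(len(fix.tiles), [(e.src, e.dst) for e in edges],
                       [true[e.dst] - true[e.src] for e in edges])
        solved = solve_section(g, fix.tiles)
        assert solved.residual_norms.max() < 1e-6

    def test_replaced_weight_changes_solution(self):
        """The weighting path is live: conflicting replaced edge moves
        the solution differently at weight 0.5 vs 1.0."""
        from hexalign.lss import DeltaGraph, solve
        edges = [(0, 1), (1, 2), (0, 2)]
        deltas = [(100.0, 0), (100.0, 0), (260.0, 0)]  # inconsistent loop
        s1 = solve(DeltaGraph(3, edges, deltas, [1, 1, 1.0]))
        s2 = solve(DeltaGraph(3, edges, deltas, [1, 1, 0.5]))
        assert not np.allclose(s1.coords, s2.coords)

    def test_single_tile_montage_is_identity(self):
        img = (np.random.default_rng(0).random((64, 64)) * 255).astype(np.uint8)
        tile = Tile(img, 0, 0, (0.0, 0.0), PX)
        sec = render_montage([tile], np.zeros((1, 2)))
        assert np.array_equal(sec.image, img)

    def test_overlap_partition_of_unity(self):
        """Two tiles with identical overlap content: blended output
        equals that content exactly."""
        rng = np.random.default_rng(1)
        strip = (rng.random((64, 112)) * 255).astype(np.uint8)
        left = Tile(strip[:, :64], 0, 0, (32 * PX, 32 * PX), PX)
        right = Tile(strip[:, 48:], 0, 1, ((48 + 32) * PX, 32 * PX), PX)
        coords = np.array([[32 * PX, 32 * PX], [(48 + 32) * PX, 32 * PX]])
        sec = render_montage([left, right], coords)
        assert np.array_equal(sec.image, strip)

    def test_montage_order_invariance(self, small_tile_fixture):
        fix = small_tile_fixture
        edges = build_neighbor_graph(fix.tiles, fix.layout)
        sec1 = render_montage(fix.tiles, fix.true_positions, edges=edges)
        perm = np.random.default_rng(3).permutation(len(fix.tiles))
        tiles2 = [fix.tiles[i] for i in perm]
        sec2 = render_montage(tiles2, fix.true_positions[perm])
        assert sec1.image.shape == sec2.image.shape
        # identical content except feather-ramp rounding at overlaps
        assert np.abs(sec1.image.astype(int) - sec2.image.astype(int)).max() <= 1

    def test_reconstruction_against_phantom(self, small_tile_fixture):
        fix = small_tile_fixture
        section, *_ = montage_section(fix.tiles, fix.layout)
        corr, mae = montage_vs_phantom(section, fix)
        assert corr > 0.98
        assert mae < 2.0
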