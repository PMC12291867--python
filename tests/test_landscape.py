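"""Buffers, landscape metrics and the driver table."""

import numpy as np
import pytest

from betadrivers import LandUseGrid, PipelineConfig, ValidationError
from betadrivers.landscape import (
    driver_table,
    extract_buffer,
    hails,
    landuse_proportions,
    metric_contag,
    metric_lpi,
    metric_shdi,
    patch_label,
)
from betadrivers.core_io import SiteRecord


def grid_from(codes, cellsize=10.0, xll=0.0, yll=0.0):
    return LandUseGrid(np.asarray(codes, dtype=np.int64), cellsize, xll, yll)


def uniform_grid(n, code=1, cellsize=10.0):
    return grid_from(np.full((n, n), code), cellsize=cellsize)


def centre_of_cell(grid, row, col):
    x = grid.xll + (col + 0.5) * grid.cellsize
    y = grid.yll + (grid.nrows - 1 - row + 0.5) * grid.cellsize
    return x, y


class TestExtractBuffer:
    def test_nine_cells_at_radius_one_and_a_half(self):
        g = uniform_grid(11)
        mask = extract_buffer(g, centre_of_cell(g, 5, 5), 1.5 * g.cellsize)
        assert mask.sum() == 9  # centres with dx^2+dy^2 <= 2.25 cells^2

    def test_radius_covering_whole_grid(self):
        g = uniform_grid(5)
        with pytest.warns(UserWarning):
            mask = extract_buffer(g, centre_of_cell(g, 2, 2), 500.0)
        assert mask.all()

    def test_radius_below_cellsize_rejected(self):
        g = uniform_grid(5)
        with pytest.raises(ValidationError):
            extract_buffer(g, centre_of_cell(g, 2, 2), 5.0)

    def test_deterministic(self):
        g = uniform_grid(9)
        site = centre_of_cell(g, 4, 4)
        np.testing.assert_array_equal(
            extract_buffer(g, site, 25.0), extract_buffer(g, site, 25.0)
        )


class TestProportions:
    def test_single_class(self):
        g = uniform_grid(5, code=3)
        props = landuse_proportions(g, np.ones((5, 5), bool))
        assert props == {3: 1.0}

    def test_half_and_half(self):
        codes = np.ones((4, 4), int)
        codes[:, 2:] = 2
        props = landuse_proportions(grid_from(codes), np.ones((4, 4), bool))
        assert props[1] == props[2] == 0.5

    def test_translation_invariance(self):
        codes = np.arange(16).reshape(4, 4) % 7 + 1
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        a = landuse_proportions(grid_from(codes, xll=0), mask)
        b = landuse_proportions(grid_from(codes, xll=1e6, yll=-5e5), mask)
        assert a == b

    def test_all_nodata_rejected(self):
        g = grid_from(np.full((3, 3), -9999))
        with pytest.raises(ValidationError):
            landuse_proportions(g, np.ones((3, 3), bool))


class TestPatches:
    def test_single_class_single_patch(self):
        g = uniform_grid(4)
        patches = patch_label(g, np.ones((4, 4), bool))
        assert patches.max() == 1

    def test_diagonal_cells_connect(self):
        codes = np.array([[1, 2], [2, 1]])
        patches = patch_label(grid_from(codes), np.ones((2, 2), bool))
        # each class's diagonal pair merges under 8-connectivity
        assert patches.max() == 2

    def test_checkerboard_two_patches(self):
        codes = (np.indices((6, 6)).sum(axis=0) % 2) + 1
        patches = patch_label(grid_from(codes), np.ones((6, 6), bool))
        assert patches.max() == 2


class TestMetrics:
    def test_lpi(self):
        codes = np.ones((10, 10), int)
        codes[:3, :] = 2  # 30-cell patch vs 70-cell patch
        mask = np.ones((10, 10), bool)
        g = grid_from(codes)
        assert metric_lpi(patch_label(g, mask), mask) == pytest.approx(70.0)
        assert metric_lpi(patch_label(uniform_grid(5), mask[:5, :5]), mask[:5, :5]) == 100.0

    def test_shdi(self):
        assert metric_shdi([1.0]) == 0.0
        assert metric_shdi([0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-6)
        m = 7
        assert metric_shdi([1 / m] * m) == pytest.approx(np.log(m))

    def test_contag_single_class_is_100(self):
        g = uniform_grid(5)
        assert metric_contag(g, np.ones((5, 5), bool)) == 100.0

    def test_contag_checkerboard_matches_bruteforce_oracle(self):
        codes = (np.indices((8, 8)).sum(axis=0) % 2) + 1
        g = grid_from(codes)
        mask = np.ones((8, 8), bool)
        # independent oracle: enumerate 4-neighbour adjacencies cell by cell
        gmat = np.zeros((2, 2))
        for r in range(8):
            for c in range(8):
                for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 8 and 0 <= cc < 8:
                        gmat[codes[r, c] - 1, codes[rr, cc] - 1] += 1
        p = np.array([0.5, 0.5])
        pstar = p[:, None] * gmat / gmat.sum(axis=1, keepdims=True)
        terms = pstar[pstar > 0]
        expected = (1 + (terms * np.log(terms)).sum() / (2 * np.log(2))) * 100
        assert metric_contag(g, mask) == pytest.approx(expected, abs=1e-10)

    def test_contag_increases_with_aggregation(self):
        """Randomly interspersed cells (adjacency mass spread over all
        class combinations) score below two solid blocks of the same
        composition; SHDI, which sees composition only, is unchanged."""
        rng = np.random.default_rng(0)
        interleaved = rng.permuted(np.repeat([1, 2], 32)).reshape(8, 8)
        blocks = np.ones((8, 8), int)
        blocks[:, 4:] = 2
        mask = np.ones((8, 8), bool)
        c_int = metric_contag(grid_from(interleaved), mask)
        c_blk = metric_contag(grid_from(blocks), mask)
        assert c_blk > c_int
        p_int = landuse_proportions(grid_from(interleaved), mask)
        p_blk = landuse_proportions(grid_from(blocks), mask)
        assert metric_shdi(p_int) == pytest.approx(metric_shdi(p_blk))


class TestHails:
    def test_pure_construction_and_zero_coefficients(self):
        ci = {"construction": 1.0, "grass": 0.0}
        names = {4: "construction", 3: "grass"}
        assert hails({4: 1.0}, ci, names) == 100.0
        assert hails({3: 1.0}, ci, names) == 0.0

    def test_weighted_mix(self):
        ci = {"construction": 1.0, "grass": 0.067}
        names = {4: "construction", 3: "grass"}
        assert hails({4: 0.5, 3: 0.5}, ci, names) == pytest.approx(53.35)

    def test_missing_coefficient_named(self):
        with pytest.raises(ValidationError, match="5"):
            hails({5: 1.0}, {"construction": 1.0}, {5: "water"})


class TestDriverTable:
    def test_eleven_columns_and_determinism(self, bundle):
        t = driver_table(bundle.grid, bundle.sites[:5], 1000.0, bundle.config)
        assert t.shape == (5, 11)
        assert t.attrs["radius_m"] == 1000.0
        t2 = driver_table(bundle.grid, bundle.sites[:5], 1000.0, bundle.config)
        np.testing.assert_allclose(t.to_numpy(), t2.to_numpy())

    def test_homogeneous_landscape_zero_variance(self):
        g = uniform_grid(60, code=2, cellsize=100.0)
        sites = [
            SiteRecord(f"S{i}", 0.0, 0.0, 0.0, x=x, y=3000.0)
            for i, x in enumerate((2500.0, 3000.0, 3500.0))
        ]
        t = driver_table(g, sites, 1000.0, PipelineConfig())
        assert np.allclose(t.to_numpy().std(axis=0), 0.0)

    def test_class_relabelling_invariance(self, rng):
        codes = rng.integers(1, 3, size=(30, 30))
        g = grid_from(codes, cellsize=100.0)
        swap = {1: 2, 2: 1}
        g2 = grid_from(np.vectorize(swap.get)(codes), cellsize=100.0)
        names = {1: "cultivated", 2: "forest"}
        names_sw = {1: "forest", 2: "cultivated"}
        mask = extract_buffer(g, (1500.0, 1500.0), 800.0)
        p1 = landuse_proportions(g, mask, classes=[1, 2])
        p2 = landuse_proportions(g2, mask, classes=[1, 2])
        assert p1[1] == p2[2] and p1[2] == p2[1]
        ci = {"cultivated": 0.2, "forest": 0.067}
        assert hails(p1, ci, names) == pytest.approx(hails(p2, ci, names_sw))
        assert metric_contag(g, mask) == pytest.approx(metric_contag(g2, mask))


def test_ascii_grid_roundtrip(tmp_path, rng):
    codes = rng.integers(1, 8, size=(12, 9))
    g = LandUseGrid(codes, 25.0, xll=100.0, yll=-50.0)
    g.to_ascii(tmp_path / "g.asc")
    g2 = LandUseGrid.from_ascii(tmp_path / "g.asc")
    np.testing.assert_array_equal(g.codes, g2.codes)
    assert (g2.cellsize, g2.xll, g2.yll) == (25.0, 100.0, -50.0)
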