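"""Point-grid canopy sampling: design rules, QC, and estimator calibration."""

import math

import numpy as np
import pytest

import ufcarbon as uf
from ufcarbon.canopy import (
    CANOPY,
    CLOUD,
    OTHER_URBAN,
    Cell,
    SamplePoint,
    iter_cells,
)


def make_grid(data, resolution=100.0):
    return uf.LandcoverGrid(data=np.asarray(data, dtype=int), resolution=resolution)


def uniform_grid(value, cells_shape=(10, 10), px=10, resolution=100.0):
    rows, cols = cells_shape[0] * px, cells_shape[1] * px
    return make_grid(np.full((rows, cols), value), resolution)


class TestGridIO:
    @pytest.mark.parametrize("name", ["grid.txt", "grid.tif"])
    def test_round_trip(self, tmp_path, name):
        grid, _ = uf.generate_raster(0.4, extent=(30, 30), seed=5)
        path = tmp_path / name
        from ufcarbon.canopy import write_grid

        write_grid(grid, path)
        back = uf.read_grid(path, resolution=grid.resolution)
        assert (back.data == grid.data).all()


class TestSelectCells:
    def test_quarter_rate_on_all_urban_grid(self):
        grid = uniform_grid(OTHER_URBAN)  # 10x10 cells of 1 km2
        assert len(uf.select_cells(grid, sampling_rate=0.25, seed=0)) == 25

    def test_full_rate_selects_every_qualifying_cell(self):
        grid = uniform_grid(CANOPY)
        assert len(uf.select_cells(grid, sampling_rate=1.0, seed=0)) == 100

    def test_low_urban_cells_discarded(self):
        # every cell exactly 20% urban -> below the >25% rule -> nothing
        block = np.zeros((10, 10), dtype=int)
        block[:2, :] = OTHER_URBAN
        grid = make_grid(np.tile(block, (5, 5)))
        assert uf.select_cells(grid, seed=0) == []
        est = uf.estimate_grid_canopy(grid, seed=0)
        assert est.fraction is None and est.n_used == 0

    def test_boundary_is_strict(self):
        # exactly 25% urban is still discarded; just above passes
        block = np.zeros((10, 10), dtype=int)
        block.ravel()[:25] = OTHER_URBAN
        assert uf.select_cells(make_grid(np.tile(block, (2, 2))), seed=0) == []
        block.ravel()[25] = OTHER_URBAN
        assert len(uf.select_cells(make_grid(np.tile(block, (2, 2))), sampling_rate=1.0, seed=0)) == 4

    def test_deterministic_for_fixed_seed(self):
        grid = uniform_grid(OTHER_URBAN)
        a = uf.select_cells(grid, sampling_rate=0.25, seed=42)
        b = uf.select_cells(grid, sampling_rate=0.25, seed=42)
        assert a == b

    def test_empty_grid_errors(self):
        grid = make_grid(np.full((5, 5), OTHER_URBAN), resolution=100.0)
        with pytest.raises(uf.UFCarbonError):
            uf.select_cells(grid, cell_size_km=1.0)  # smaller than one cell


class TestPlacePoints:
    CELL = Cell(index=(0, 0), row0=0, col0=0, row1=110, col1=110)

    def test_default_count_and_lattice(self):
        pts = uf.place_points(self.CELL, 55)
        assert len(pts) == 55
        rows = {r for r, _ in pts}
        cols = {c for _, c in pts}
        assert (len(rows), len(cols)) == (5, 11)  # closest-to-square lattice

    def test_single_point_is_cell_centre(self):
        assert uf.place_points(self.CELL, 1) == [(55, 55)]

    def test_adjacent_cells_have_disjoint_points(self):
        other = Cell(index=(0, 1), row0=0, col0=110, row1=110, col1=220)
        assert not set(uf.place_points(self.CELL)) & set(uf.place_points(other))

    def test_points_stay_inside_cell(self):
        for r, c in uf.place_points(self.CELL, 55):
            assert 0 <= r < 110 and 0 <= c < 110


class TestEstimateCanopy:
    @staticmethod
    def points(n_canopy, n_other, n_cloud=0, cell=(0, 0)):
        pts = []
        for i in range(n_canopy):
            pts.append(SamplePoint(0, i, CANOPY, cell))
        for i in range(n_other):
            pts.append(SamplePoint(1, i, OTHER_URBAN, cell))
        for i in range(n_cloud):
            pts.append(
                SamplePoint(2, i, CLOUD, cell, discarded=True, reason="cloud_or_distortion")
            )
        return pts

    def test_all_canopy(self):
        est = uf.estimate_canopy(self.points(10, 0))
        assert est.fraction == 1.0 and est.se == 0.0

    def test_cloud_points_removed_before_estimation(self):
        est = uf.estimate_canopy(self.points(22, 28, n_cloud=5))
        assert est.fraction == pytest.approx(22 / 50)
        assert est.n_used == 50 and est.n_discarded == 5

    def test_all_discarded_is_no_data(self):
        with pytest.raises(uf.NoDataError):
            uf.estimate_canopy(self.points(0, 0, n_cloud=7))

    def test_binomial_se(self):
        est = uf.estimate_canopy(self.points(30, 70))
        assert est.se == pytest.approx(math.sqrt(0.3 * 0.7 / 100))


@pytest.fixture(scope="module")
def raster():
    grid, realized = uf.generate_raster(0.30, extent=(200, 200), seed=7, resolution=50.0)
    return grid, realized


class TestCalibration:
    """Sampling-design properties on synthetic rasters."""

    def test_unbiased_over_seeds(self, raster):
        grid, _ = raster
        # exact target: mean over all cells of the lattice-point canopy share
        cells = list(iter_cells(grid, 1.0))
        per_cell = [
            np.mean([grid.data[r, c] == CANOPY for r, c in uf.place_points(cell, 55)])
            for cell in cells
        ]
        target = float(np.mean(per_cell))
        ests = [
            uf.estimate_grid_canopy(grid, sampling_rate=0.25, seed=s).fraction
            for s in range(200)
        ]
        mc_se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - target) < 2 * mc_se

    def test_estimate_close_to_truth_with_many_points(self, raster):
        grid, realized = raster
        est = uf.estimate_grid_canopy(grid, sampling_rate=1.0, seed=0)
        assert est.n_used >= 5000 * 0.1  # 16 cells x 55 points on this extent
        assert abs(est.fraction - realized) <= 3 * est.se

    def test_nominal_95_ci_coverage(self):
        # binomial point labels at p=0.3, n=1100 per replicate
        rng = np.random.default_rng(2024)
        p, n, reps = 0.3, 1100, 1000
        covered = 0
        for _ in range(reps):
            labels = rng.random(n) < p
            pts = [
                SamplePoint(0, i, CANOPY if hit else OTHER_URBAN, (0, 0))
                for i, hit in enumerate(labels)
            ]
            est = uf.estimate_canopy(pts)
            covered += abs(est.fraction - p) <= 1.96 * est.se
        assert 0.93 <= covered / reps <= 0.97

    def test_cluster_se_reported_with_multiple_cells(self, raster):
        grid, _ = raster
        est = uf.estimate_grid_canopy(grid, sampling_rate=1.0, seed=0)
        assert est.se_cluster is not None and est.se_cluster > 0

    def test_full_design_deterministic(self, raster):
        grid, _ = raster
        a = uf.estimate_grid_canopy(grid, sampling_rate=0.25, seed=11)
        b = uf.estimate_grid_canopy(grid, sampling_rate=0.25, seed=11)
        assert a == b
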