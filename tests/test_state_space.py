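"""Embedding, grid partitioning and symbolization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempomem.signal_models import TimeSeries
from tempomem.state_space import (
    GridPartition,
    delay_embed,
    fit_grid,
    fit_grid_occupancy,
    nonlinear_transform,
    symbolize,
    trajectory_from_series,
)


class TestDelayEmbed:
    def test_two_dimensional_embedding(self):
        traj = delay_embed(TimeSeries([1, 2, 3, 4, 5]), m=2, l=1)
        np.testing.assert_array_equal(traj.points, [[1, 2], [2, 3], [3, 4], [4, 5]])

    def test_m_one_is_identity(self):
        traj = delay_embed(TimeSeries([3.0, 1.0, 2.0]), m=1)
        np.testing.assert_array_equal(traj.points[:, 0], [3, 1, 2])

    def test_too_short_series_reports_minimum(self):
        with pytest.raises(ValueError, match="at least 31"):
            delay_embed(TimeSeries(np.arange(10.0)), m=3, l=15)

    @given(st.lists(st.floats(-100, 100), min_size=8, max_size=40),
           st.integers(2, 3), st.integers(1, 2))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_first_coordinate_reproduces_series(self, vals, m, l):
        traj = delay_embed(TimeSeries(vals), m=m, l=l)
        n_pts = len(vals) - (m - 1) * l
        np.testing.assert_array_equal(traj.points[:, 0], vals[:n_pts])


class TestNonlinearTransform:
    def test_cubic_values(self):
        traj = trajectory_from_series(TimeSeries([-1.0, 0.0, 2.0]))
        out = nonlinear_transform(traj, "cubic")
        np.testing.assert_array_equal(out.points[:, 0], [-1, 0, 8])

    def test_quadratic_preserves_sign(self):
        traj = trajectory_from_series(TimeSeries([-2.0, 3.0]))
        out = nonlinear_transform(traj, "quadratic")
        np.testing.assert_array_equal(out.points[:, 0], [-4, 9])

    def test_distinct_points_stay_distinct(self):
        vals = np.array([-1.5, -0.2, 0.0, 0.2, 1.5])
        traj = trajectory_from_series(TimeSeries(vals))
        for kind in ("quadratic", "cubic"):
            out = nonlinear_transform(traj, kind).points[:, 0]
            assert np.all(np.diff(out) > 0)


class TestFitGrid:
    @pytest.mark.parametrize("total,per_dim", [(900, 30), (2500, 50)])
    def test_square_totals_give_square_grids(self, total, per_dim):
        rng = np.random.default_rng(0)
        traj = trajectory_from_series(TimeSeries(rng.random((100, 2))))
        part = fit_grid(traj, n_cells_total=total)
        assert part.counts.tolist() == [per_dim, per_dim]

    def test_one_dimensional_equal_cells(self):
        traj = trajectory_from_series(TimeSeries(np.array([0.0, 1.0, 0.3, 0.6])))
        part = fit_grid(traj, n_cells_total=4, bounds=(np.array([0.0]), np.array([1.0])))
        sym = symbolize(traj, part)
        assert sym.symbols.tolist() == [0, 3, 1, 2]

    def test_degenerate_dimension_is_named(self):
        pts = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="dimension 1"):
            fit_grid(trajectory_from_series(TimeSeries(pts)), n_cells_total=100)

    def test_occupancy_calibration_hits_target(self):
        rng = np.random.default_rng(1)
        traj = trajectory_from_series(TimeSeries(rng.random(5000)))
        part = fit_grid_occupancy(traj, 200)
        occupied = np.unique(part.cell_of(traj.points)).size
        assert abs(occupied - 200) <= 5

    def test_occupancy_saturates_on_periodic_orbit(self):
        traj = trajectory_from_series(TimeSeries(np.tile([0.1, 0.5, 0.9], 50)))
        part = fit_grid_occupancy(traj, 100)
        assert np.unique(part.cell_of(traj.points)).size == 3


class TestSymbolize:
    def test_boundary_point_maps_to_top_cell(self):
        traj = trajectory_from_series(TimeSeries(np.array([0.0, 0.5, 1.0])))
        part = GridPartition([0.0], [1.0], [2])
        assert part.cell_of(traj.points).tolist() == [0, 1, 1]

    def test_point_outside_bounds_rejected(self):
        part = GridPartition([0.0], [1.0], [4])
        with pytest.raises(ValueError, match="outside"):
            part.cell_of(np.array([[1.5]]))

    def test_dimension_mismatch_rejected(self):
        traj = trajectory_from_series(TimeSeries(np.random.default_rng(0).random((5, 2))))
        part = GridPartition([0.0], [1.0], [4])
        with pytest.raises(ValueError, match="dimension"):
            symbolize(traj, part)

    def test_cell_centers_lie_within_half_a_cell(self):
        rng = np.random.default_rng(2)
        traj = trajectory_from_series(TimeSeries(rng.random((200, 2))))
        part = fit_grid(traj, n_cells_total=100)
        cells = part.cell_of(traj.points)
        centers = part.cell_center(cells)
        assert np.all(np.abs(centers - traj.points) <= part.widths / 2 + 1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_refining_the_grid_never_merges_symbols(self, seed):
        rng = np.random.default_rng(seed)
        traj = trajectory_from_series(TimeSeries(rng.random((50, 2))))
        coarse = fit_grid(traj, per_dim=(4, 4))
        fine = fit_grid(traj, per_dim=(8, 8))
        sc = coarse.cell_of(traj.points)
        sf = fine.cell_of(traj.points)
        for fine_cell in np.unique(sf):
            assert np.unique(sc[sf == fine_cell]).size == 1

    def test_partition_json_round_trip(self, tmp_path):
        part = GridPartition([0.0, -1.0], [2.0, 3.0], [10, 20])
        path = tmp_path / "part.json"
        part.save_json(path)
        back = GridPartition.load_json(path)
        np.testing.assert_array_equal(back.lows, part.lows)
        np.testing.assert_array_equal(back.highs, part.highs)
        np.testing.assert_array_equal(back.counts, part.counts)
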