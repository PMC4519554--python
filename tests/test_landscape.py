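"""Tension-spline interpolation, divergence surfaces and raster round trips."""

import numpy as np
import pytest
from scipy.special import expn
from shapely.geometry import Polygon

from geohet.landscape import (
    DivergenceSummary,
    PointLayer,
    Surface,
    build_point_layer,
    divergence_landscape,
    evaluate_rst_at,
    interpolate_rst,
    rank_models,
    read_ascii_grid,
    surface_summary,
    write_ascii_grid,
)
from geohet.regionalization import LandUnit, RegionSet


def square_unit(uid, x0, y0, size=10.0, sub=None):
    poly = Polygon([(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)])
    return LandUnit(unit_id=uid, name=uid, polygon=poly, sub_centroids=sub)


class TestPointLayer:
    def test_sub_centroids_replicate_the_unit_value(self):
        sub = [(float(i), 5.0) for i in range(14)]
        region = RegionSet(units=[square_unit("city", 0, 0, sub=sub)])
        layer = build_point_layer(region, {"city": 44.0})
        assert len(layer.points) == 14
        assert all(v == 44.0 for _, v in layer.points)

    def test_flag_off_gives_one_point_per_unit(self):
        sub = [(float(i), 5.0) for i in range(14)]
        region = RegionSet(units=[square_unit("city", 0, 0, sub=sub),
                                  square_unit("b", 10, 0)])
        layer = build_point_layer(region, {"city": 1.0, "b": 2.0},
                                  replicate_sub_centroids=False)
        assert len(layer.points) == 2

    def test_thirteen_units_one_with_fourteen_anchors(self):
        units = [square_unit(f"u{i}", 10.0 * i, 0) for i in range(13)]
        units[0].sub_centroids = [(float(i), 5.0) for i in range(14)]
        region = RegionSet(units=units)
        layer = build_point_layer(region, {f"u{i}": float(i) for i in range(13)})
        assert len(layer.points) == 26

    def test_missing_value_omits_point_with_warning(self):
        region = RegionSet(units=[square_unit("a", 0, 0), square_unit("b", 10, 0)])
        with pytest.warns(UserWarning, match="point omitted"):
            layer = build_point_layer(region, {"a": 1.0})
        assert len(layer.points) == 1


@pytest.fixture(scope="module")
def random_layer():
    rng = np.random.default_rng(13)
    pts = rng.uniform(0, 1000, size=(5, 2))
    vals = rng.normal(44.0, 0.5, size=5)
    return PointLayer(points=[((x, y), v) for (x, y), v in zip(pts, vals)])


class TestRST:
    def test_constant_data_reproduced_everywhere(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(6, 2))
        layer = PointLayer(points=[((x, y), 7.5) for x, y in pts])
        s = interpolate_rst(layer, (0, 0), 10.0, 10, 10, smoothing=0.0)
        assert np.abs(s.values - 7.5).max() < 1e-6

    def test_exact_interpolation_at_zero_smoothing(self, random_layer):
        z = evaluate_rst_at(random_layer, random_layer.coords(), smoothing=0.0)
        np.testing.assert_allclose(z, random_layer.data(), atol=1e-6)

    def test_agrees_with_independent_dense_solve(self, random_layer):
        """Loop-based re-derivation of the spline system, using expn for E1."""
        xy = random_layer.coords()
        z = random_layer.data()
        tension = 40.0
        ext = max(xy[:, 0].max() - xy[:, 0].min(), xy[:, 1].max() - xy[:, 1].min())
        phi = tension / ext

        def basis(r):
            if r == 0:
                return 0.0
            rho = (phi * r / 2.0) ** 2
            return -(np.log(rho) + expn(1, rho) + np.euler_gamma)

        m = len(xy)
        A = np.zeros((m + 1, m + 1))
        for i in range(m):
            for j in range(m):
                A[i, j] = basis(np.hypot(*(xy[i] - xy[j])))
            A[i, m] = A[m, i] = 1.0
        sol = np.linalg.solve(A, np.append(z, 0.0))
        probes = np.array([[100.0, 200.0], [555.0, 321.0], [900.0, 50.0]])
        expected = [
            sum(sol[j] * basis(np.hypot(*(p - xy[j]))) for j in range(m)) + sol[m]
            for p in probes
        ]
        got = evaluate_rst_at(random_layer, probes, tension=tension, smoothing=0.0)
        np.testing.assert_allclose(got, expected, rtol=1e-9)
        at_data = evaluate_rst_at(random_layer, xy, tension=tension, smoothing=0.0)
        np.testing.assert_allclose(at_data, z, atol=1e-6)

    def test_probe_converges_to_data_value(self, random_layer):
        xy = random_layer.coords()
        target = random_layer.data()[0]
        offsets = [10.0, 1.0, 0.01]
        errs = [
            abs(evaluate_rst_at(random_layer, xy[:1] + d, smoothing=0.0)[0] - target)
            for d in offsets
        ]
        assert errs[-1] < 1e-3
        assert errs[2] <= errs[0]

    def test_coincident_points_need_smoothing(self):
        layer = PointLayer(points=[((0.0, 0.0), 1.0), ((0.0, 0.0), 2.0), ((5.0, 5.0), 3.0)])
        with pytest.raises(ValueError, match="smoothing"):
            interpolate_rst(layer, (0, 0), 1.0, 5, 5, smoothing=0.0)

    def test_too_few_points_rejected(self):
        layer = PointLayer(points=[((0.0, 0.0), 1.0), ((1.0, 1.0), 2.0)])
        with pytest.raises(ValueError, match="at least 3"):
            interpolate_rst(layer, (0, 0), 1.0, 5, 5)

    def test_smoothing_relaxes_interpolation(self, random_layer):
        smooth = evaluate_rst_at(random_layer, random_layer.coords(), smoothing=0.5)
        exact = random_layer.data()
        assert np.abs(smooth - exact).max() > 1e-6  # no longer pinned to data


def flat_surface(values, origin=(0.0, 0.0), cell=1.0):
    return Surface(origin=origin, cell_size=cell, values=np.asarray(values, dtype=float))


class TestDivergence:
    def test_printed_extremes_give_range(self):
        observed = flat_surface([[45.00, 43.36]])
        predicted = flat_surface([[44.0, 44.0]])
        _, max_rg = divergence_landscape(observed, predicted)
        assert max_rg == pytest.approx(1.64)

    def test_identical_surfaces_give_zero(self):
        obs = flat_surface([[1.0, 2.0], [3.0, 4.0]])
        div, _ = divergence_landscape(obs, flat_surface([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(div.values, 0.0)

    def test_half_range_cell_is_fifty_percent(self):
        obs = flat_surface([[45.00, 43.36, 44.18]])
        pred = flat_surface([[45.00, 43.36, 43.36]])
        div, max_rg = divergence_landscape(obs, pred)
        assert div.values[0, 2] == pytest.approx(50.0)

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(9)
        a = flat_surface(rng.normal(44, 1, (4, 4)))
        b = flat_surface(rng.normal(44, 1, (4, 4)))
        d_ab, _ = divergence_landscape(a, b)
        # |a-b| is symmetric in the sign of the difference
        diff = np.abs(a.values - b.values)
        np.testing.assert_allclose(d_ab.values * (a.values.max() - a.values.min()) / 100,
                                   diff)
        shift_a = flat_surface(a.values + 5.0)
        shift_b = flat_surface(b.values + 5.0)
        d_shift, _ = divergence_landscape(shift_a, shift_b)
        np.testing.assert_allclose(d_shift.values, d_ab.values)

    def test_nodata_propagates(self):
        obs = flat_surface([[1.0, np.nan], [3.0, 4.0]])
        div, _ = divergence_landscape(obs, flat_surface([[1.0, 1.0], [1.0, 1.0]]))
        assert np.isnan(div.values[0, 1])

    def test_incongruent_grids_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            divergence_landscape(flat_surface([[1.0, 2.0]]), flat_surface([[1.0]]))

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            divergence_landscape(flat_surface([[2.0, 2.0]]), flat_surface([[1.0, 1.0]]))


class TestSummaryAndRanking:
    def test_constant_surface(self):
        stats = surface_summary(flat_surface(np.full((3, 3), 4.0)))
        assert stats["mean"] == stats["median"] == stats["min"] == stats["max"] == 4.0
        assert stats["sd"] == 0.0

    def test_two_by_two_hand_computation(self):
        stats = surface_summary(flat_surface([[0.0, 0.0], [100.0, 100.0]]))
        assert stats["mean"] == 50.0 and stats["median"] == 50.0

    def test_nodata_half_excluded(self):
        vals = np.array([[1.0, 1.0], [np.nan, np.nan]])
        stats = surface_summary(flat_surface(vals))
        assert stats["mean"] == 1.0 and stats["sd"] == 0.0

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="no valid cells"):
            surface_summary(flat_surface([[np.nan]]))

    def test_rank_models_on_printed_means(self):
        sums = [
            DivergenceSummary("m1", 17.0, 14.9, 15.0, 0.0, 70.6),
            DivergenceSummary("m2", 10.0, 7.6, 9.0, 0.0, 36.6),
            DivergenceSummary("m3", 13.2, 8.4, 12.0, 0.0, 38.4),
            DivergenceSummary("m4", 11.8, 8.2, 11.0, 0.0, 39.9),
        ]
        best, ranking = rank_models(sums)
        assert best == "m2"
        assert [s.model_id for s in ranking] == ["m2", "m4", "m3", "m1"]

    def test_single_summary_wins(self):
        s = DivergenceSummary("only", 5.0, 1.0, 5.0, 0.0, 9.0)
        assert rank_models([s])[0] == "only"

    def test_sd_breaks_ties(self):
        a = DivergenceSummary("a", 5.0, 5.0, 5.0, 0.0, 9.0)
        b = DivergenceSummary("b", 5.0, 4.0, 5.0, 0.0, 9.0)
        assert rank_models([a, b])[0] == "b"


def test_ascii_grid_round_trip(tmp_path):
    vals = np.array([[1.5, np.nan], [3.25, 4.0]])
    s = Surface(origin=(100.0, 200.0), cell_size=50.0, values=vals)
    path = tmp_path / "grid.asc"
    write_ascii_grid(s, path)
    text = path.read_text()
    for key in ("ncols 2", "nrows 2", "xllcorner", "yllcorner", "cellsize", "NODATA_value"):
        assert key in text
    back = read_ascii_grid(path)
    assert back.origin == s.origin and back.cell_size == s.cell_size
    np.testing.assert_allclose(back.values, s.values, equal_nan=True)


def test_clip_masks_outside_cells():
    s = flat_surface(np.ones((4, 4)))
    mask = Polygon([(0, 0), (2, 0), (2, 4), (0, 4)])  # left half
    clipped = s.clip(mask)
    assert np.isnan(clipped.values[:, 2:]).all()
    assert np.isfinite(clipped.values[:, :2]).all()
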