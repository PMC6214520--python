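"""Hazard rescaling, zonal aggregation against the brute-force oracle, filtering."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

import fire_equity as fe
from fire_equity.hazard import classify_whp

from conftest import brute_force_zonal


def make_raster(values, mask=None, **kw):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return fe.HazardRaster(values, mask, **kw)


class TestRescale:
    def test_endpoints_map_to_unit_interval(self):
        r = make_raster([[2.0, 7.0]])
        out = fe.rescale_hazard(r, 2.0, 7.0)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]])

    def test_classed_input_linear_map(self):
        r = make_raster([[0, 1, 2], [3, 4, 5]])
        out = fe.rescale_hazard(r, 0, 5)
        np.testing.assert_allclose(out.values, [[0, 0.2, 0.4], [0.6, 0.8, 1.0]])

    def test_already_unit_scale_identity(self):
        vals = np.random.default_rng(0).uniform(size=(4, 4))
        out = fe.rescale_hazard(make_raster(vals), 0.0, 1.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_masked_cells_become_zero_but_stay_flagged(self):
        mask = np.array([[False, True]])
        r = make_raster([[5.0, 123.0]], mask=mask)
        out = fe.rescale_hazard(r, 0.0, 10.0)
        assert out.values[0, 1] == 0.0
        assert out.mask[0, 1]

    def test_invalid_range_rejected(self):
        with pytest.raises(fe.InvalidConfigError):
            fe.rescale_hazard(make_raster([[1.0]]), 3.0, 3.0)

    def test_out_of_range_value_names_cell(self):
        r = make_raster([[0.5, 9.0]])
        with pytest.raises(fe.DataError, match="row 0, col 1"):
            fe.rescale_hazard(r, 0.0, 1.0)


class TestZonalMean:
    def test_constant_field(self):
        r = make_raster(np.full((6, 6), 0.4))
        zm = fe.zonal_mean(r, [("t", box(0, 0, 6, 6))])
        assert zm["whp"].iloc[0] == pytest.approx(0.4)
        assert zm["n_cells"].iloc[0] == 36

    def test_2x2_hand_mean(self):
        r = make_raster([[0.0, 0.2], [0.4, 0.6]])
        zm = fe.zonal_mean(r, [("t", box(0, 0, 2, 2))])
        assert zm["whp"].iloc[0] == pytest.approx(0.3)

    def test_sliver_polygon_missing_with_warning(self):
        r = make_raster(np.ones((4, 4)))
        sliver = Polygon([(0.9, 0.9), (0.95, 0.9), (0.95, 0.95)])
        with pytest.warns(UserWarning, match="no cell centers"):
            zm = fe.zonal_mean(r, [("big", box(0, 0, 4, 4)), ("sliver", sliver)])
        assert np.isnan(zm.set_index("tract_id").loc["sliver", "whp"])
        assert zm.set_index("tract_id").loc["big", "n_cells"] == 16

    def test_empty_tract_set_rejected(self):
        with pytest.raises(fe.InvalidConfigError):
            fe.zonal_mean(make_raster(np.ones((2, 2))), [])

    def test_no_overlap_rejected(self):
        r = make_raster(np.ones((2, 2)))
        with pytest.raises(fe.DataError):
            fe.zonal_mean(r, [("far", box(100, 100, 110, 110))])

    def test_nonburnable_included_as_zero_or_excluded(self):
        vals = np.array([[0.8, 0.4], [0.0, 0.4]])
        mask = np.array([[False, False], [True, False]])
        r = make_raster(vals, mask=mask)
        tracts = [("t", box(0, 0, 2, 2))]
        inc = fe.zonal_mean(r, tracts, include_nonburnable=True)
        exc = fe.zonal_mean(r, tracts, include_nonburnable=False)
        assert inc["whp"].iloc[0] == pytest.approx(1.6 / 4)
        assert exc["whp"].iloc[0] == pytest.approx(1.6 / 3)
        assert exc["n_cells"].iloc[0] == 3

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_oracle(self, trial):
        """Random small rasters/tessellations agree exactly with the per-cell oracle,
        including cut lines placed exactly on cell centers (boundary rule)."""
        rng = np.random.default_rng(trial)
        nrows, ncols = rng.integers(4, 20, size=2)
        vals = rng.uniform(size=(nrows, ncols))
        mask = rng.random((nrows, ncols)) < 0.1
        vals[mask] = 0.0
        r = make_raster(vals, mask=mask)
        # random 2-3 x 2-3 rectangular tessellation; half the trials put cut
        # lines exactly through cell centers to exercise the half-open rule
        nx, ny = rng.integers(2, 4, size=2)
        if trial % 2 == 0:
            xcuts = np.sort(rng.uniform(0, ncols, size=nx - 1))
            ycuts = np.sort(rng.uniform(0, nrows, size=ny - 1))
        else:
            xcuts = np.sort(rng.choice(np.arange(ncols) + 0.5, size=nx - 1, replace=False))
            ycuts = np.sort(rng.choice(np.arange(nrows) + 0.5, size=ny - 1, replace=False))
        xs = [0.0, *xcuts, float(ncols)]
        ys = [0.0, *ycuts, float(nrows)]
        tracts = [
            (f"t{i}_{j}", box(xs[i], ys[j], xs[i + 1], ys[j + 1]))
            for i in range(len(xs) - 1)
            for j in range(len(ys) - 1)
        ]
        include = bool(trial % 3)
        got = fe.zonal_mean(r, tracts, include_nonburnable=include)
        oracle = brute_force_zonal(r, tracts, include_nonburnable=include)
        for _, row in got.iterrows():
            o_mean, o_n = oracle[row["tract_id"]]
            assert row["n_cells"] == o_n
            if o_n:
                assert row["whp"] == o_mean  # exact, same floating sum order not required
            else:
                assert np.isnan(row["whp"])

    def test_cell_partition_no_double_counting(self, small_bundle):
        zm = small_bundle.tract_hazard
        raster = small_bundle.raster
        assert zm["n_cells"].sum() == raster.values.size

    def test_rescale_commutes_with_zonal_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(2, 8, size=(10, 10))
        r = make_raster(vals)
        tracts = [("a", box(0, 0, 5, 10)), ("b", box(5, 0, 10, 10))]
        zm_then = fe.zonal_mean(fe.rescale_hazard(r, 2, 8), tracts)["whp"]
        then_zm = (fe.zonal_mean(r, tracts)["whp"] - 2) / 6
        np.testing.assert_allclose(zm_then, then_zm, atol=1e-12)


class TestFilter:
    def test_inclusive_boundary(self):
        df = pd.DataFrame({"tract_id": list("abc"), "whp": [0.1, 0.3, 0.5],
                           "n_cells": [1, 1, 1]})
        kept = fe.filter_at_least_moderate(df, 0.3)
        assert set(kept["tract_id"]) == {"b", "c"}

    def test_empty_result_is_an_error(self):
        df = pd.DataFrame({"tract_id": list("ab"), "whp": [0.1, 0.2]})
        with pytest.raises(fe.DataError, match="threshold"):
            fe.filter_at_least_moderate(df, 1.0)

    def test_bad_threshold_rejected(self):
        df = pd.DataFrame({"tract_id": list("ab"), "whp": [0.5, 0.6]})
        with pytest.raises(fe.InvalidConfigError):
            fe.filter_at_least_moderate(df, 0.0)


class TestAsciiGridRoundTrip:
    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        vals = rng.uniform(size=(7, 5))
        mask = rng.random((7, 5)) < 0.2
        vals[mask] = 0.0
        r = make_raster(vals, mask=mask, xllcorner=-3.5, yllcorner=10.0, cellsize=0.25)
        path = tmp_path / "grid.asc"
        fe.write_ascii_grid(r, path)
        back = fe.read_ascii_grid(path)
        np.testing.assert_array_equal(back.values, r.values)
        np.testing.assert_array_equal(back.mask, r.mask)
        assert back.cellsize == 0.25 and back.xllcorner == -3.5

    def test_classify_whp(self):
        assert classify_whp(0.0) == "non-burnable"
        assert classify_whp(0.1) == "very low"
        assert classify_whp(0.4) == "moderate"  # boundary takes higher class
        assert classify_whp(0.45) == "moderate"
        assert classify_whp(1.0) == "very high"
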